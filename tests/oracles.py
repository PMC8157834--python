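"""Independent scalar-loop reference implementations used as test oracles.

Deliberately written entry-by-entry with plain Python arithmetic, sharing
no code with the package, so agreement is meaningful.
"""

from __future__ import annotations


def brute_force_crosstalk(
    counts: list[list[int]],
    gamma: float,
    tau: float,
    max_row_loss: float,
    min_total: int,
) -> tuple[list[list[int]], set[int]]:
    """Entry-by-entry crosstalk filter: e_i = g*C_i/N, s = e/(e+x), flag s>=tau.

    Returns the filtered matrix and the set of skipped row indices
    (rows with flagged entries protected by a guard).
    """
    n_samples = len(counts[0]) if counts else 0
    out = [row[:] for row in counts]
    skipped: set[int] = set()
    for i, row in enumerate(counts):
        total = sum(row)
        e = gamma * total / n_samples
        flagged = [
            j for j, x in enumerate(row) if x > 0 and e / (e + x) >= tau
        ]
        if not flagged:
            continue
        loss = sum(row[j] for j in flagged)
        if total < min_total or loss > max_row_loss * total:
            skipped.add(i)
            continue
        for j in flagged:
            out[i][j] = 0
    return out, skipped


def brute_force_octave_bin(count: int) -> int:
    """Bin of a count by direct doubling: k with 2^k <= count < 2^(k+1)."""
    assert count >= 1
    k = 0
    edge = 2
    while count >= edge:
        k += 1
        edge *= 2
    return k
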