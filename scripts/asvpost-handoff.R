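#!/usr/bin/env Rscript
# Assemble asvpost exports into a serialized phyloseq object.
#
# Usage:
#   Rscript scripts/asvpost-handoff.R --table feature-table.tsv \
#       [--taxonomy taxonomy.tsv] [--metadata metadata.tsv] \
#       [--tree tree.nwk] --out phyloseq.rds [--macro alpha]
#
# The table is features-as-rows TSV with the first column holding feature
# IDs; taxonomy is feature ID + rank columns; metadata is sample ID +
# attribute columns; the tree (newick) is passed to phyloseq verbatim.
# The optional "alpha" macro prints an alpha-diversity summary, as an
# example of running a canned analysis straight from the command line.

suppressMessages({
  library(optparse)
  library(phyloseq)
})

opts <- parse_args(OptionParser(option_list = list(
  make_option("--table", type = "character"),
  make_option("--taxonomy", type = "character", default = NULL),
  make_option("--metadata", type = "character", default = NULL),
  make_option("--tree", type = "character", default = NULL),
  make_option("--out", type = "character"),
  make_option("--macro", type = "character", default = NULL)
)))

if (is.null(opts$table) || is.null(opts$out)) {
  stop("--table and --out are required")
}

tab <- read.delim(opts$table, row.names = 1, check.names = FALSE)
components <- list(otu_table(as.matrix(tab), taxa_are_rows = TRUE))

if (!is.null(opts$taxonomy)) {
  tax <- read.delim(opts$taxonomy, row.names = 1, check.names = FALSE,
                    colClasses = "character")
  if (!setequal(rownames(tax), rownames(tab))) {
    stop("taxonomy feature IDs do not match the table")
  }
  components <- c(components, list(tax_table(as.matrix(tax))))
}

if (!is.null(opts$metadata)) {
  meta <- read.delim(opts$metadata, row.names = 1, check.names = FALSE)
  if (!all(colnames(tab) %in% rownames(meta))) {
    stop("metadata sample IDs do not match the table")
  }
  components <- c(components, list(sample_data(meta)))
}

if (!is.null(opts$tree)) {
  tre <- tryCatch(read_tree(opts$tree),
                  error = function(e) stop(sprintf("malformed tree %s: %s",
                                                   opts$tree, conditionMessage(e))))
  if (is.null(tre)) stop(sprintf("malformed tree: %s", opts$tree))
  components <- c(components, list(tre))
}

ps <- do.call(phyloseq, components)
saveRDS(ps, opts$out)
cat(sprintf("phyloseq object: %d taxa, %d samples -> %s\n",
            ntaxa(ps), nsamples(ps), opts$out))

if (!is.null(opts$macro) && opts$macro == "alpha") {
  div <- estimate_richness(ps, measures = c("Observed", "Shannon"))
  print(div)
}
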