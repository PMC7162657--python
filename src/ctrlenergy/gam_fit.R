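# Penalized-spline GAM fits (mgcv, REML) for a batch of features.
#
# Usage: Rscript gam_fit.R <data.tsv> <out.tsv> <mode> <covariates> <k> [group]
#   data.tsv    tab-separated; feature columns named feat_<j>, plus age,
#               covariate columns, and (mode=cognition) ef_score
#   mode        "age" or "cognition"
#   covariates  comma-separated linear covariate column names ("" for none)
#   k           spline basis dimension
#   group       optional column name: fit feat_0 separately within each
#               group level (replicate-cohort sweeps), one output row per
#               level
#
# Output: one row per feature with edf, test statistic and p-value of the
# term of interest (the age smooth, or the linear ef_score coefficient), plus
# for mode=cognition the partial correlation of ef_score with the feature
# given the age smooth and covariates (correlation of GAM residuals).

suppressPackageStartupMessages(library(mgcv))

args <- commandArgs(trailingOnly = TRUE)
data_path <- args[1]
out_path <- args[2]
mode <- args[3]
covariates <- if (nchar(args[4]) > 0) strsplit(args[4], ",")[[1]] else character(0)
k_dim <- as.integer(args[5])

group_col <- if (length(args) >= 6 && nchar(args[6]) > 0) args[6] else NULL

d <- read.delim(data_path, check.names = FALSE)
feat_cols <- grep("^feat_", names(d), value = TRUE)
cov_str <- paste(c(sprintf("s(age, k=%d, bs='cr')", k_dim), covariates),
                 collapse = " + ")

if (!is.null(group_col)) {
  levels_g <- unique(d[[group_col]])
  rows <- vector("list", length(levels_g))
  for (i in seq_along(levels_g)) {
    dg <- d[d[[group_col]] == levels_g[i], ]
    m <- gam(as.formula(paste("feat_0 ~", cov_str)), data = dg,
             method = "REML")
    st <- summary(m)$s.table
    rows[[i]] <- data.frame(feature = as.character(levels_g[i]),
                            edf = st[1, "edf"], statistic = st[1, "F"],
                            p_value = st[1, "p-value"], partial_r = NA)
  }
  write.table(do.call(rbind, rows), out_path, sep = "\t",
              row.names = FALSE, quote = FALSE)
  quit(save = "no", status = 0)
}

rows <- vector("list", length(feat_cols))
if (mode == "cognition") {
  ef_feat_resid <- resid(gam(
    as.formula(paste("ef_score ~", cov_str)), data = d, method = "REML"))
}
for (i in seq_along(feat_cols)) {
  fc <- feat_cols[i]
  if (mode == "age") {
    f <- as.formula(paste(fc, "~", cov_str))
    m <- gam(f, data = d, method = "REML")
    st <- summary(m)$s.table
    rows[[i]] <- data.frame(feature = fc, edf = st[1, "edf"],
                            statistic = st[1, "F"],
                            p_value = st[1, "p-value"], partial_r = NA)
  } else {
    f <- as.formula(paste(fc, "~ ef_score +", cov_str))
    m <- gam(f, data = d, method = "REML")
    pt <- summary(m)$p.table
    r0 <- resid(gam(as.formula(paste(fc, "~", cov_str)),
                    data = d, method = "REML"))
    pr <- cor(r0, ef_feat_resid)
    rows[[i]] <- data.frame(feature = fc,
                            edf = summary(m)$s.table[1, "edf"],
                            statistic = pt["ef_score", "t value"],
                            p_value = pt["ef_score", "Pr(>|t|)"],
                            partial_r = pr)
  }
}
out <- do.call(rbind, rows)
write.table(out, out_path, sep = "\t", row.names = FALSE, quote = FALSE)
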