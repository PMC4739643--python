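# Batch GAM/GAMM fitting driver: reads a job description (JSON) plus train /
# predict CSVs, fits each model with mgcv (REML, double-penalty shrinkage),
# and writes one JSON result file.  Invoked by energyscape.rgam.

suppressMessages({
  library(mgcv)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
job_dir <- args[[1]]

jobs <- fromJSON(file.path(job_dir, "jobs.json"), simplifyVector = FALSE)
train <- read.csv(file.path(job_dir, "train.csv"), stringsAsFactors = FALSE)
pred <- NULL
if (file.exists(file.path(job_dir, "predict.csv"))) {
  pred <- read.csv(file.path(job_dir, "predict.csv"), stringsAsFactors = FALSE)
}

for (fac in names(jobs$factors)) {
  levs <- unlist(jobs$factors[[fac]])
  train[[fac]] <- factor(train[[fac]], levels = levs)
  if (!is.null(pred) && fac %in% names(pred)) {
    pred[[fac]] <- factor(pred[[fac]], levels = levs)
  }
}

knots <- NULL
if (!is.null(jobs$knots)) {
  knots <- lapply(jobs$knots, function(v) as.numeric(unlist(v)))
}

results <- list()
for (spec in jobs$models) {
  set.seed(if (is.null(jobs$seed)) 1L else as.integer(jobs$seed))
  form <- as.formula(spec$formula)
  m <- gam(form, data = train, family = gaussian(), method = "REML",
           select = TRUE, optimizer = c("outer", "bfgs"), knots = knots)
  sm <- summary(m)
  pt <- sm$p.table
  coef_tab <- list(
    names = rownames(pt),
    est = unname(pt[, 1]), se = unname(pt[, 2]),
    t = unname(pt[, 3]), p = unname(pt[, 4])
  )
  smooth_edf <- list()
  if (length(m$smooth) > 0) {
    for (i in seq_along(m$smooth)) {
      lab <- m$smooth[[i]]$label
      idx <- m$smooth[[i]]$first.para:m$smooth[[i]]$last.para
      smooth_edf[[lab]] <- sum(m$edf[idx])
    }
  }
  res <- list(
    n = nrow(train),
    loglik = as.numeric(logLik(m)),
    edf_total = sum(m$edf),
    r2_adj = as.numeric(sm$r.sq),
    scale = as.numeric(m$sig2),
    converged = isTRUE(m$converged),
    coef = coef_tab,
    smooth_edf = smooth_edf
  )
  if (!is.null(pred) && isTRUE(spec$predict)) {
    excl <- if (is.null(spec$exclude)) NULL else unlist(spec$exclude)
    pr <- predict(m, newdata = pred, type = "response", exclude = excl,
                  newdata.guaranteed = FALSE)
    res$predictions <- as.numeric(pr)
  }
  results[[spec$name]] <- res
}

writeLines(toJSON(results, digits = NA, auto_unbox = TRUE, null = "null"),
           file.path(job_dir, "result.json"))
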