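# Batch runner for crossed random-intercept mixed models.
# Usage: Rscript fit_mixed.R jobs.json results.json
# jobs.json: [{name, data (csv path), formula, family ("gaussian"|"binomial"),
#              nagq (int, binomial only)}]
# Each result carries fixed effects, vcov, variance components, convergence
# diagnostics and a car::Anova type-III Wald table (cross-check).

suppressMessages({
  library(lme4)
  library(car)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 2) stop("usage: fit_mixed.R jobs.json results.json")
jobs <- fromJSON(args[[1]], simplifyVector = FALSE)

fit_one <- function(job) {
  d <- read.csv(job$data)
  f <- as.formula(job$formula)
  warn <- character(0)
  fit <- withCallingHandlers(
    if (identical(job$family, "binomial")) {
      glmer(f, data = d, family = binomial,
            nAGQ = if (is.null(job$nagq)) 1L else as.integer(job$nagq))
    } else {
      lmer(f, data = d, REML = FALSE)
    },
    warning = function(w) {
      warn <<- c(warn, conditionMessage(w))
      invokeRestart("muffleWarning")
    }
  )
  b <- fixef(fit)
  V <- as.matrix(vcov(fit))
  vc <- as.data.frame(VarCorr(fit))
  re_sd <- setNames(as.list(vc$sdcor[vc$grp != "Residual"]),
                    vc$grp[vc$grp != "Residual"])
  sigma_resid <- if (any(vc$grp == "Residual")) vc$sdcor[vc$grp == "Residual"] else NA
  msgs <- unlist(fit@optinfo$conv$lme4$messages)
  an <- tryCatch(
    Anova(fit, type = 3, test.statistic = "Chisq"),
    error = function(e) NULL
  )
  anova_tab <- NULL
  if (!is.null(an)) {
    anova_tab <- list(
      term = rownames(an),
      chisq = unname(an[["Chisq"]]),
      df = unname(an[["Df"]]),
      p = unname(an[[grep("^Pr", names(an), value = TRUE)[1]]])
    )
  }
  list(
    name = job$name,
    ok = TRUE,
    family = if (identical(job$family, "binomial")) "binomial" else "gaussian",
    n = nobs(fit),
    terms = names(b),
    beta = unname(b),
    vcov = V,
    re_sd = re_sd,
    sigma = sigma_resid,
    loglik = as.numeric(logLik(fit)),
    singular = isSingular(fit),
    messages = as.list(c(msgs, warn)),
    anova_type3 = anova_tab
  )
}

results <- lapply(jobs, function(job) {
  tryCatch(fit_one(job), error = function(e) {
    list(name = job$name, ok = FALSE, error = conditionMessage(e))
  })
})

writeLines(toJSON(results, digits = I(17), auto_unbox = TRUE, na = "null"),
           args[[2]])
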