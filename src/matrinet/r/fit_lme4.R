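# Batched (g)lmer fitting driver.
#
# Usage: Rscript fit_lme4.R <jobdir>
#   <jobdir>/job.json : {"formula": ..., "family": "gaussian"|"binomial", "reml": true}
#   <jobdir>/data.csv : model table with a .replicate column; factors arrive
#                       as character columns, sex as a 0/1 male indicator.
# Writes <jobdir>/coefs.csv (replicate, term, estimate, se) and
# <jobdir>/status.csv (replicate, ok, singular, messages).

suppressMessages({
  library(lme4)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
jobdir <- args[[1]]
job <- fromJSON(file.path(jobdir, "job.json"))
d <- read.csv(file.path(jobdir, "data.csv"), stringsAsFactors = TRUE)
fml <- as.formula(job$formula)

coef_rows <- list()
status_rows <- list()
for (r in sort(unique(d$.replicate))) {
  di <- droplevels(d[d$.replicate == r, ])
  msgs <- character(0)
  fit <- withCallingHandlers(
    tryCatch(
      {
        if (job$family == "binomial") {
          glmer(fml, family = binomial, data = di,
                control = glmerControl(check.conv.singular = "ignore"))
        } else {
          lmer(fml, data = di, REML = isTRUE(job$reml),
               control = lmerControl(check.conv.singular = "ignore"))
        }
      },
      error = function(e) { msgs <<- c(msgs, conditionMessage(e)); NULL }
    ),
    warning = function(w) { msgs <<- c(msgs, conditionMessage(w)); invokeRestart("muffleWarning") },
    message = function(m) { msgs <<- c(msgs, conditionMessage(m)); invokeRestart("muffleMessage") }
  )
  ok <- !is.null(fit)
  singular <- ok && isSingular(fit)
  if (ok) {
    cf <- summary(fit)$coefficients
    coef_rows[[length(coef_rows) + 1]] <- data.frame(
      replicate = r,
      term = rownames(cf),
      estimate = cf[, "Estimate"],
      se = cf[, "Std. Error"],
      row.names = NULL
    )
  }
  status_rows[[length(status_rows) + 1]] <- data.frame(
    replicate = r,
    ok = ok,
    singular = singular,
    messages = paste(unique(msgs), collapse = " | ")
  )
}

if (length(coef_rows)) {
  write.csv(do.call(rbind, coef_rows), file.path(jobdir, "coefs.csv"), row.names = FALSE)
} else {
  write.csv(data.frame(replicate = integer(), term = character(),
                       estimate = numeric(), se = numeric()),
            file.path(jobdir, "coefs.csv"), row.names = FALSE)
}
write.csv(do.call(rbind, status_rows), file.path(jobdir, "status.csv"), row.names = FALSE)
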