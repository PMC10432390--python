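# Worker script for facemetrics.mixed_models: fits a rating-level linear
# mixed-effects model (REML, Satterthwaite df via lmerTest) and computes
# single-step (Tukey-style) post hoc contrasts via multcomp::glht.
# Called as: Rscript lmm_fit.R <config.json>
# config: data_csv, out_json, response, predictors[], group_col, rater_col,
#         face_col, group_levels[], random_slopes (bool), contrast_terms[]

suppressMessages({
  library(lmerTest)
  library(multcomp)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
cfg <- fromJSON(args[[1]], simplifyVector = TRUE)

dat <- read.csv(cfg$data_csv, stringsAsFactors = FALSE)
dat$.group <- factor(dat[[cfg$group_col]], levels = cfg$group_levels)
dat$.rater <- interaction(dat$.group, factor(dat[[cfg$rater_col]]), drop = TRUE)
dat$.face <- factor(dat[[cfg$face_col]])

preds <- cfg$predictors
if (nlevels(dat$.group) > 1) {
  fixed <- paste0("(", paste(preds, collapse = " + "), ") * .group")
} else {
  fixed <- paste(preds, collapse = " + ")
}
if (isTRUE(cfg$random_slopes)) {
  ran <- paste0("(1 + ", paste(preds, collapse = " + "), " | .rater) + (1 | .face)")
} else {
  ran <- "(1 | .rater) + (1 | .face)"
}
form <- as.formula(paste(cfg$response, "~", fixed, "+", ran))

fit <- lmer(form, data = dat, REML = TRUE,
            control = lmerControl(optimizer = "bobyqa",
                                  optCtrl = list(maxfun = 2e5),
                                  calc.derivs = FALSE))

coefs <- as.data.frame(summary(fit)$coefficients)
names(coefs) <- c("estimate", "se", "df", "t", "p")
coefs$term <- sub("\\.group", "ratergroup", rownames(coefs))
rownames(coefs) <- NULL

vc <- as.data.frame(VarCorr(fit))
vc$grp <- sub("^\\.", "", vc$grp)
vc$var1 <- sub("\\.group", "ratergroup", ifelse(is.na(vc$var1), "", vc$var1))
vc$var2 <- sub("\\.group", "ratergroup", ifelse(is.na(vc$var2), "", vc$var2))
rownames(vc) <- NULL

msgs <- fit@optinfo$conv$lme4$messages
if (is.null(msgs)) msgs <- character(0)

# Pairwise contrasts among the group levels for each requested term family.
# multcomp's single-step p-values integrate a multivariate t distribution by
# Monte Carlo; fix the RNG so repeated fits are bit-identical.
set.seed(20230816)
non_ref <- cfg$group_levels[-1]
contrasts_out <- list()
for (term in cfg$contrast_terms) {
  coef_of <- function(g) {
    if (term == "group") paste0(".group", g) else paste0(term, ":.group", g)
  }
  cn <- names(fixef(fit))
  K <- NULL
  labs <- c()
  lev <- cfg$group_levels
  for (i in seq_along(lev)) for (j in seq_len(i - 1)) {
    a <- lev[[i]]; b <- lev[[j]]  # contrast a - b
    row <- setNames(rep(0, length(cn)), cn)
    if (a != lev[[1]]) row[coef_of(a)] <- 1
    if (b != lev[[1]]) row[coef_of(b)] <- -1
    K <- rbind(K, row)
    labs <- c(labs, paste0(a, "-", b))
  }
  rownames(K) <- labs
  gl <- glht(fit, linfct = K)
  adj <- summary(gl)  # single-step adjustment (Tukey-style family)
  raw <- summary(gl, test = adjusted("none"))
  contrasts_out[[term]] <- data.frame(
    pair = labs,
    estimate = as.numeric(adj$test$coefficients),
    se = as.numeric(adj$test$sigma),
    p_adjusted = as.numeric(adj$test$pvalues),
    p_unadjusted = as.numeric(raw$test$pvalues)
  )
}

out <- list(
  fixed = coefs[, c("term", "estimate", "se", "df", "t", "p")],
  random = vc[, c("grp", "var1", "var2", "vcov", "sdcor")],
  loglik = as.numeric(logLik(fit)),
  singular = isSingular(fit),
  messages = msgs,
  n_obs = nrow(dat),
  contrasts = contrasts_out
)
write(toJSON(out, dataframe = "columns", digits = 12, auto_unbox = TRUE),
      cfg$out_json)
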