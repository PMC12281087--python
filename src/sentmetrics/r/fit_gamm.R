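# Fit one or more penalized-spline additive mixed models (mgcv) and emit JSON.
# Usage: Rscript fit_gamm.R <data.tsv> <specs.json> <out.json>
# specs.json: {"<name>": {"formula": "...", "factors": [...], "smooth_vars": [...],
#              "grid_points": 100, "ci_level": 0.99}, ...}

suppressMessages({
  library(mgcv)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 3) stop("usage: fit_gamm.R data.tsv specs.json out.json")
data_path <- args[1]; specs_path <- args[2]; out_path <- args[3]

d <- read.delim(data_path, stringsAsFactors = FALSE, check.names = FALSE)
specs <- fromJSON(specs_path, simplifyVector = TRUE)

results <- list()
for (name in names(specs)) {
  spec <- specs[[name]]
  for (f in spec$factors) d[[f]] <- factor(d[[f]])
  fit <- tryCatch(
    gam(as.formula(spec$formula), data = d, method = "REML"),
    error = function(e) e
  )
  if (inherits(fit, "error")) {
    results[[name]] <- list(error = conditionMessage(fit))
    next
  }
  if (!fit$converged) {
    results[[name]] <- list(error = "smoothing-parameter estimation did not converge")
    next
  }
  s <- summary(fit)

  smooth_terms <- list()
  if (!is.null(s$s.table) && nrow(s$s.table) > 0) {
    for (i in seq_len(nrow(s$s.table))) {
      smooth_terms[[rownames(s$s.table)[i]]] <- list(
        edf = unname(s$s.table[i, "edf"]),
        F = unname(s$s.table[i, "F"]),
        p = unname(s$s.table[i, "p-value"])
      )
    }
  }
  parametric <- list()
  if (!is.null(s$p.table) && nrow(s$p.table) > 0) {
    for (i in seq_len(nrow(s$p.table))) {
      parametric[[rownames(s$p.table)[i]]] <- list(
        estimate = unname(s$p.table[i, 1]),
        p = unname(s$p.table[i, 4])
      )
    }
  }

  # Partial effects: each numeric smooth on a grid over its observed range,
  # other covariates pinned (numeric -> median, factor -> first level).
  grid_n <- if (is.null(spec$grid_points)) 100 else spec$grid_points
  ci <- if (is.null(spec$ci_level)) 0.99 else spec$ci_level
  crit <- qnorm(1 - (1 - ci) / 2)
  partials <- list()
  mf <- model.frame(fit)
  for (v in spec$smooth_vars) {
    term_label <- paste0("s(", v, ")")
    x <- d[[v]]
    grid <- seq(min(x, na.rm = TRUE), max(x, na.rm = TRUE), length.out = grid_n)
    nd <- d[rep(1, grid_n), , drop = FALSE]
    for (cn in names(nd)) {
      if (is.factor(nd[[cn]])) {
        nd[[cn]] <- factor(rep(levels(d[[cn]])[1], grid_n), levels = levels(d[[cn]]))
      } else if (is.numeric(nd[[cn]])) {
        nd[[cn]] <- rep(median(d[[cn]], na.rm = TRUE), grid_n)
      }
    }
    nd[[v]] <- grid
    pr <- predict(fit, newdata = nd, type = "terms", terms = term_label, se.fit = TRUE)
    eff <- as.numeric(pr$fit[, 1])
    se <- as.numeric(pr$se.fit[, 1])
    partials[[v]] <- list(
      grid = grid, effect = eff,
      lower = eff - crit * se, upper = eff + crit * se
    )
  }

  results[[name]] <- list(
    aic = AIC(fit),
    n_obs = length(fit$y),
    converged = fit$converged,
    coefficients = as.numeric(coef(fit)),
    smooth_terms = smooth_terms,
    parametric = parametric,
    partial_effects = partials
  )
}

writeLines(toJSON(results, digits = I(12), auto_unbox = TRUE, null = "null"), out_path)
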