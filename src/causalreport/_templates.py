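"""Versioned text resources for the report.

Every user-facing sentence lives here so wording changes are diffable.
Placeholders: {adj} adjustment set (comma-joined, user order), {a}
exposure name, {y} outcome name, {lvl} exposure level, {ref} reference
level.
"""

TEMPLATE_VERSION = "1"

EXCHANGEABILITY = (
    '[1] Conditional exchangeability requires that adjusting for "{adj}" is '
    'sufficient to eliminate all confounding and selection bias between '
    '"{a}" and "{y}." See the covariate balance table '
    "($Assumptions$exchangeability$covariate_balance) in the saved output "
    "and the corresponding explanations "
    "($Assumptions$exchangeability$explanation)."
)

EXCHANGEABILITY_MARGINAL = (
    "[1] Unconditional exchangeability requires that units with "
    '"{a}"={lvl} and "{a}"={ref} are exchangeable without any adjustment: '
    'there is no confounding or selection bias between "{a}" and "{y}." '
    "No adjustment set was specified (marginal estimand). See the "
    "corresponding explanations ($Assumptions$exchangeability$explanation)."
)

POSITIVITY = (
    "[2] Positivity: is satisfied when both exposed and unexposed "
    "individuals are observed within every stratum of variables adjusted "
    "for ({adj}). This can be evaluated using the propensity plots saved "
    "in the output at $Assumptions$positivity$plots, the table below "
    "($Assumptions$positivity$ps_table) and the corresponding explanation "
    "at $Assumptions$positivity$explanation."
)

POSITIVITY_MARGINAL = (
    "[2] Positivity: is satisfied when both levels of \"{a}\" are observed "
    "in the study population. The adjustment set is empty, so the marginal "
    "condition applies: no covariate stratum is involved. The propensity "
    "summary ($Assumptions$positivity$ps_table) reduces to the sample "
    "exposure proportion; see $Assumptions$positivity$explanation."
)

CONSISTENCY = (
    "[3] Consistency: implies that exposure '{a}' must be sufficiently "
    "well-defined so that any variation within the definition of the "
    "exposure would not result in a different outcome. See "
    "$Assumptions$consistency$explanation for a more in-depth explanation "
    "and examples."
)

NO_INTERFERENCE = (
    '[4] No Interference: assumes that the exposure "{a}" applied to one '
    "unit does not affect the outcome of other units."
)

NO_MEASUREMENT_ERROR = (
    "[5] No measurement error: assumes that all variables were measured "
    "without substantial error, such that no substantial measurement bias "
    "is present. See $Assumptions$no_measurement_error$explanation for a "
    "further discussion."
)

WELL_SPECIFIED = (
    "[6] Well-specified models: assumes that any models used are "
    "well-specified meaning that they include all relevant non-linearities "
    "and/or statistical interactions."
)

ASSUMPTIONS_PREAMBLE = (
    "To interpret these effects as causal, the following key assumptions "
    "must be satisfied:"
)

DISAGREEMENT_NOTE = (
    "Please evaluate whether the difference between the lowest estimate: "
    "{low:.4f} and highest: {high:.4f} is of substance, given the nature "
    "of the data. If so, evaluate the different modeling assumptions "
    "underlying each estimator."
)

ESTIMAND_POINTER = "*Please see output at $Estimand_interpretation for details"

EXPLANATION_EXCHANGEABILITY = (
    "Exchangeability means the exposed and unexposed groups are comparable: "
    "within levels of the adjustment set, which exposure a unit received "
    "carries no information about its potential outcomes. Violations arise "
    "from unmeasured confounding and from selection into the sample. The "
    "covariate balance table reports standardized mean differences for "
    "every adjustment covariate before and after inverse-probability "
    "weighting; |SMD| > 0.1 after weighting suggests the propensity model "
    "has not balanced that covariate. Balance on measured covariates can "
    "never demonstrate balance on unmeasured ones."
)

EXPLANATION_POSITIVITY = (
    "Positivity requires every covariate pattern to have a positive "
    "probability of each exposure level. Estimated propensity scores close "
    "to 0 or 1, or arms whose score distributions barely overlap, indicate "
    "near-violations: estimates then rest on extrapolation and weights "
    "become unstable. The summary table shows the per-arm range of the "
    "estimated score; the overlap data give the full distributions."
)

EXPLANATION_CONSISTENCY = (
    "Consistency links the observed outcome to the counterfactual: for a "
    "unit that actually received exposure level a, the observed outcome "
    "equals the potential outcome under a. It fails when the exposure is "
    "vaguely defined and different versions of it would produce different "
    "outcomes (for example, 'quitting smoking' abruptly versus gradually). "
    "No statistic can test it; it is a matter of subject-matter definition."
)

EXPLANATION_NO_MEASUREMENT_ERROR = (
    "Measurement error in the exposure, the outcome, or the adjustment "
    "covariates can bias the effect estimate in either direction; error in "
    "a confounder leaves residual confounding even after adjustment. This "
    "analysis takes all variables at face value."
)

METHODS_PARAGRAPH = (
    "We estimated the average treatment effect of {a} (level {lvl} versus "
    "{ref}) on {y}{adj_clause}, using outcome regression, inverse "
    "probability of treatment weighting, S- and T-standardization, and "
    "targeted maximum likelihood estimation. A causal interpretation of "
    "these estimates requires: (1) conditional exchangeability, i.e. that "
    "{adj_or_nothing} suffices to remove confounding and selection bias "
    "between {a} and {y}; (2) positivity, i.e. that both levels of {a} "
    "occur at every covariate pattern; (3) consistency, i.e. that {a} is "
    "well-defined; (4) no interference between units; (5) no measurement "
    "error in {y}, {a} or the covariates; and (6) well-specified models."
)
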