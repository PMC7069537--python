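"""CV-tuned Lasso logistic fit on the packaged synthetic cohort.

Prints the tuning parameter selected by 10-fold cross-validation and the
surviving (nonzero) coefficients as odds ratios: variables the penalty did
not zero out are the model's mortality risk factors.
"""

from lassologit import cv_select_lambda, encode_design, fit_lasso, read_cohort
from lassologit.report import coefficient_report, render_coefficient_report
from lassologit.simulate import packaged_cohort_path

dm = encode_design(read_cohort(packaged_cohort_path()))
cv = cv_select_lambda(dm.X, dm.y, n_folds=10, seed=1)
fit = fit_lasso(dm.X, dm.y, cv.lambda_min)

print(f"lambda_min (10-fold CV): {cv.lambda_min:.4f}")
print(f"{fit.active_set.size} of {dm.p} covariates kept\n")
print(render_coefficient_report(coefficient_report(dm.column_names, fit.beta),
                                "Lasso logistic"))
print("\nOR > 1: higher odds of death; OR < 1: protective.")
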