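"""Factor reduction of a clinical laboratory panel.

Extracts principal components of the correlation matrix, keeps factors
with eigenvalue > 1 (Kaiser), applies varimax rotation, classifies
loadings (weak/moderate/strong) and computes regression-method factor
scores — the data-reduction step that turns collinear laboratory panels
into a few interpretable covariates for the growth model.
"""
import numpy as np

from ordgrowth.factors import classify_loadings, extract_components, score_factors, varimax_rotate
from ordgrowth.simulate import default_panel, simulate_clinical_panel

panel = default_panel()  # 6 white-cell variables on 3 planted factors
X = simulate_clinical_panel(
    panel["loadings"], n=4000, noise_sd=panel["noise_sd"], seed=3,
    variable_names=panel["variables"],
)

sol = extract_components(X)
rot = varimax_rotate(sol)
print("eigenvalues:", np.round(sol.eigenvalues, 2))
print(f"retained factors: {len(rot.factor_names)}, "
      f"cumulative variance explained: {rot.variance_explained:.0%}")

frame = rot.loadings_frame().round(3)
frame["strength"] = [" / ".join(row) for row in classify_loadings(rot.loadings)]
print(frame.to_string())

scores = score_factors(X, rot)
print("factor score SDs:", np.round(scores.std(axis=0), 2))
# The granulocyte and mononuclear blocks are recovered with strong
# loadings on their own factors.  The planted eosinophil component has a
# single indicator, so its eigenvalue hovers at 1 and the strict Kaiser
# rule (eigenvalue > 1) drops it — a known blind spot of the criterion
# for single-variable factors.
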