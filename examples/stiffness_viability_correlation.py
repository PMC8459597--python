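"""Fit the stiffness -> ultrasound-sensitivity line across cell lines.

Uses per-line mean moduli and post-exposure viabilities as (E, V) points,
fits the linear model, and predicts viability for an unseen stiffness.
"""

import cellelast as ce

# (mean Young's modulus kPa, viability % after a 2.8 J/cm^2 exposure)
points = [
    (34.0, 95.0),   # stiff non-cancerous keratinocytes
    (6.2, 27.0),    # soft head-and-neck carcinoma line
]
model = ce.fit_sensitivity(points)
print(f"slope = {model.slope:.3f} %/kPa, intercept = {model.intercept:.1f} %, "
      f"R^2 = {model.r_squared:.2f} (n = {model.n_points})")

for e in (1.6, 20.1, 34.0):
    v, clamped = model.predict(e)
    tag = " (clamped)" if clamped else ""
    print(f"  predicted viability at E = {e:5.1f} kPa: {v:5.1f} %{tag}")
# Softer cells are predicted less viable after the same exposure: the
# single mechanical parameter orders the lines by ultrasound sensitivity.
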