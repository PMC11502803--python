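"""Flory-exponent recovery on reference polymer ensembles.

The scaling relation r(s) = b * s**nu links mean internal distance to
residue separation: nu = 1/3 for a globule, 1/2 for an ideal chain, ~3/5
for an expanded (self-avoiding) coil, 1 for a rod.  Each generator below
has a known ground-truth exponent, so the fitted values validate the
whole scaling pipeline.
"""

import ctdphase as cp

print(f"{'ensemble':>8} {'nu_fit':>7} {'b_fit':>6}   nominal")
for kind, n_conf, nominal, kwargs in [
    ("ideal", 300, "1/2", {}),
    ("rod", 5, "1", {}),
    ("globule", 150, "1/3", {}),
    ("saw", 100, "~0.588 (3/5)", {"max_sep": 61}),
]:
    spec = cp.EnsembleSpec(366, n_conf, kind=kind, segment_length=0.55, seed=1)
    profile = cp.internal_distance_profile(cp.generate_ensemble(spec))
    fit = cp.fit_flory(profile, mode="free", **kwargs)
    print(f"{kind:>8} {fit.nu:7.3f} {fit.b:6.3f}   {nominal}")

# clamped-prefactor fit restricted to separations > 200 peptide bonds
spec = cp.EnsembleSpec(366, 300, kind="ideal", segment_length=0.55, seed=2)
profile = cp.internal_distance_profile(cp.generate_ensemble(spec))
fit = cp.fit_flory(profile, mode="paper")
print(f"\npaper-mode fit on ideal chains (b clamped to 0.55 nm, s > 200): "
      f"nu = {fit.nu:.3f}")
print("an exponent near 0.5 means the analysis reproduces ideal-chain "
      "statistics without bias")
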