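"""Build a condition cohort and compare the covariate schemes.

Shows the inclusion filters (65+, 12 months of prior enrollment), the
99.5% winsorization cap, and how the same diagnoses turn into different
candidate-variable sets: grouped condition categories (pooled, index-only,
or channel-separated) versus individual frequency-filtered codes.
"""

import payrisk as pr

bundle = pr.generate_bundle(pr.SimConfig(n_patients=5_000, seed=7))
cohort = pr.build_cohort(bundle, "HF")
print(f"HF cohort: {len(cohort)} admissions "
      f"(of {(bundle.index_admissions['condition'] == 'HF').sum()} HF index stays)")
print(f"winsorization cap (99.5%): ${cohort.attrs['winsor_cap']:,.0f}")
print("age bands:", cohort["age_band"].value_counts().to_dict())

maps = pr.load_toy_maps()
for name in pr.SCHEME_NAMES:
    d = pr.build_design(cohort, bundle, pr.Scheme(name, maps))
    comorb = len(d.columns) - len(d.forced)
    print(f"  {name:20s} {comorb:3d} comorbidity columns "
          f"(+{len(d.forced)} forced age bands)")
print("A column count difference between codes_index and "
      "codes_index_history reflects the separate history channel; "
      "hcc_separate doubles categories seen in both channels.")
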