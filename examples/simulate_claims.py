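"""Generate a synthetic claims bundle and round-trip it through CSV.

The generator draws index admissions for three condition cohorts, index
and 12-month-history diagnoses with POA flags, and 30-day payments from
each condition's GLM family/link; ground truth is recorded for recovery
tests.
"""

from pathlib import Path

import payrisk as pr

cfg = pr.SimConfig(n_patients=5_000, n_hospitals=60, seed=7)
bundle = pr.generate_bundle(cfg)

adm = bundle.index_admissions
print(f"admissions: {len(adm)}, hospitals: {adm['hospital_id'].nunique()}, "
      f"diagnosis rows: {len(bundle.diagnoses)}")
print("condition mix:", adm["condition"].value_counts().to_dict())
for cond, grp in adm.groupby("condition"):
    print(f"  {cond}: mean payment ${grp['payment_30d'].mean():,.0f} "
          f"(SD ${grp['payment_30d'].std():,.0f})")
small = (adm["hospital_id"].value_counts() < 25).mean()
print(f"hospitals under the 25-case threshold: {small:.0%}")
print("patients without 12 months of prior enrollment:",
      int((bundle.enrollment["prior_ffs_months"] < 12).sum()))

out = Path("scratch/example_bundle")
pr.write_bundle(bundle, out)
assert pr.read_bundle(out) == bundle
print(f"round-tripped through {out}/ without loss")
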