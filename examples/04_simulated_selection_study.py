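"""Does split-antigen MSC selection reduce repeated amino-acid mismatches?

Simulates paired synthetic cohorts at equal seeds — one drawing MSC donors
blind, one rejecting candidates with any repeated split-antigen mismatch at
HLA-A/B/DR/DQ — and compares the resulting repeated amino-acid loads. The
ground truth comes from the brute-force oracle, so the numbers are
generator facts, not engine output.
"""
import numpy as np

from hlarepeat import (AllelePool, SimulationConfig, load_packaged_store,
                       simulate_triads)

store = load_packaged_store()
pool = AllelePool.from_store(store)

unselected, selected, flagged = [], [], 0
n_cohorts = 100
for seed in range(n_cohorts):
    blind = simulate_triads(pool, SimulationConfig(
        n_patients=5, selection_policy="none", seed=seed))
    policy = simulate_triads(pool, SimulationConfig(
        n_patients=5, selection_policy="avoid-repeated-split", seed=seed,
        msc_pool_size=15))
    unselected.extend(r.total_repeated_aa() for r in blind.reports)
    selected.extend(r.total_repeated_aa() for r in policy.reports)
    flagged += len(policy.flagged)

print(f"{n_cohorts} paired cohorts of 5 patients "
      f"({len(selected)} triads per arm)")
print(f"mean total repeated aa mismatches, no selection      : "
      f"{np.mean(unselected):.2f}")
print(f"mean total repeated aa mismatches, split-avoidance   : "
      f"{np.mean(selected):.2f}")
print(f"patients with an accepted (flagged) split repeat     : {flagged}")
print(f"triads with >0 repeated aa despite selection         : "
      f"{int(np.sum(np.asarray(selected) > 0))}")
print("\nSelection lowers the repeated amino-acid load but does not remove")
print("it: epitope-level repeats persist behind clean antigen-level matches.")
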