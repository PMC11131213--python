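#!/usr/bin/env python
"""Causal-effect recovery and pleiotropy discrimination.

Part 1: under the causal scenario (true effect 0.2 on 50 valid instruments,
5e5-sample outcome), the mean IVW estimate and 95% CI coverage over 200
replicates. Part 2: the MR-Egger intercept under balanced vs directional
pleiotropy of equal spread — mean intercept and intercept-test power.
"""

import json
from pathlib import Path

from mrscreen.studies import causal_recovery, pleiotropy_discrimination

ROOT = Path(__file__).resolve().parents[1]
(ROOT / "results").mkdir(exist_ok=True)

rec = causal_recovery(n_reps=200, seed=20_240_529)
print(f"causal scenario (true beta = {rec['true_beta']}, {rec['n_reps']} replicates):")
print(f"  mean IVW estimate {rec['mean_ivw_estimate']:.4f} "
      f"(SD {rec['sd_ivw_estimate']:.4f})")
print(f"  95% CI coverage   {rec['ci95_coverage']:.3f}")

ple = pleiotropy_discrimination(n_reps=150, seed=20_240_530)
print(f"\npleiotropy discrimination ({ple['n_reps']} replicates per mode, "
      f"directional mean = {ple['pleio_mean_directional']}):")
for tag in ("balanced", "directional"):
    print(f"  {tag:<12s} mean Egger intercept {ple[f'mean_intercept_{tag}']:+.5f} "
          f"(SEM {ple[f'sem_intercept_{tag}']:.5f}), "
          f"intercept-test power {ple[f'intercept_power_{tag}']:.3f}")

payload = {"causal_recovery": rec, "pleiotropy_discrimination": ple}
(ROOT / "results" / "effect_recovery.json").write_text(json.dumps(payload, indent=2))
print("\n-> results/effect_recovery.json")
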