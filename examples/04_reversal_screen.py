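"""Screen a perturbation-signature library for reversal of a disease profile.

Concordance is the Pearson correlation between the profile's LFCs and a
signature's LFCs over shared genes; signatures below the (negative) cutoff
are candidate reversers. An approved-drug filter keeps only repurposable
perturbagens.
"""

import numpy as np

from revscreen.containers import DiseaseProfile
from revscreen.screen import ScreenConfig, filter_approved, screen_signatures
from revscreen.simulate import simulate_signature_library

rng = np.random.default_rng(0)
lfc = rng.uniform(1.0, 4.0, 200) * rng.choice([-1, 1], 200)
profile = DiseaseProfile({f"G{i:04d}": float(v) for i, v in enumerate(lfc)})

# 12 drugs spanning strong reversers (rho near 1) to disease mimics (rho < 0)
rhos = list(np.round(np.linspace(-0.5, 1.0, 12), 2))
sigs, truth = simulate_signature_library(profile, 12, 3, rhos,
                                         noise_sd=0.3, missing_prob=0.2, seed=1)

cfg = ScreenConfig(default_cutoff=-0.2, min_overlap=10)
retained = screen_signatures(profile, sigs, cfg)
print(f"{len(retained)} of {len(sigs)} signatures pass concordance < {cfg.default_cutoff}")
best = retained[0]
print(f"strongest reversal: {best.signature_id} ({best.perturbagen}), "
      f"concordance {best.concordance:.3f} over {best.n_overlap} genes "
      f"(planted rho = {truth.drug_rho[best.perturbagen]})")

approved = {d for d, r in truth.drug_rho.items() if r > 0}  # pretend list
kept = filter_approved(retained, approved)
print(f"{len(kept)} signatures remain after the approved-drug filter")
# Negative concordance means the drug pushes profile genes in the opposite
# direction to the disease; the cutoff controls how strong that push must be.
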