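"""PMax/PMin binding-site similarity from sorted distance lists.

Compares an epitope site with a rigid-body copy of itself (scores must be
exactly 1.0 — intra-site distances are rotation-invariant) and with a
heavily jittered copy, then applies the clustering decision rule:
similar iff PMax or PMin is 1.0, or PMin >= 0.9 and PMax >= 0.6.
"""

import numpy as np

from immunobench import make_site_pair, pocketmatch_score, sites_similar
from immunobench.interface import EpitopeSite


def site(coords, name):
    return EpitopeSite(residues=[("G", i) for i in range(len(coords))],
                       coords=np.asarray(coords, float), complex_ref=name)


rng = np.random.default_rng(0)
template = rng.uniform(0, 15, size=(14, 3))  # 14 heavy atoms -> 91 distances

original, rigid_copy = make_site_pair(template, jitter=0.0)
score = pocketmatch_score(site(original, "a"), site(rigid_copy, "b"))
print(f"rigid copy:    PMax={score.pmax:.3f} PMin={score.pmin:.3f} "
      f"matched={score.matched}/{score.pairs_a} -> similar: "
      f"{sites_similar(score)}")

_, noisy = make_site_pair(template, jitter=4.0, rng=rng)
score = pocketmatch_score(site(original, "a"), site(noisy, "c"))
print(f"4 A jitter:    PMax={score.pmax:.3f} PMin={score.pmin:.3f} "
      f"matched={score.matched}/{score.pairs_a} -> similar: "
      f"{sites_similar(score)}")

smaller = site(template[:6], "d")  # a sub-site: PMin uses the smaller site
score = pocketmatch_score(site(template, "a"), smaller)
print(f"6-atom subset: PMax={score.pmax:.3f} PMin={score.pmin:.3f} "
      f"-> similar: {sites_similar(score)}")
print("-> the subset matches all of its own distances (PMin = 1.0), so the"
      " rule clusters it with the full site.")
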