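"""Enumerate the bottom-up and top-down model families.

Builds the six-region base network, enumerates both families, and
prints the family partition with its uniform-family priors.
"""

import emodcm as e

base = e.build_base_network()
print(f"base network: {base.n_connections()} directed couplings, "
      f"driving input at (IOG, all_faces)")

models = e.build_model_space()
part = e.build_family_partition(models)
print(f"model space: {len(models)} models "
      f"({part.family_sizes()['BU']} bottom-up, "
      f"{part.family_sizes()['TD']} top-down)")

bu_prior = part.model_prior[part.families["BU"][0]]
td_prior = part.model_prior[part.families["TD"][0]]
print(f"per-model priors: BU {bu_prior:.4f}, TD {td_prior:.4f} "
      f"(each family holds half the prior mass)")

# the four-pathway bottom-up model sparing FUS->OFC
m = next(m for m in models
         if m.modulated_sources == ("IOG", "SPL", "HPC", "AMG"))
print(f"example: model {m.model_id} ({m.family}) modulates "
      f"{', '.join(m.modulated_sources)} -> OFC")
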