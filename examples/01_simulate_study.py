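"""Generate a synthetic aneuploidy cohort and inspect its ground truth.

Builds a small multi-karyotype study (45,X / 46,XX / 46,XY / 47,XXY in one
tissue), with circRNA counts carrying an attenuated PAR dosage effect
(alpha = 0.5), and prints what was planted.
"""

import circdosage as cd

config = cd.SimConfig(n_per_group=5, tissues=("blood",), n_circ=300,
                      circ_attenuation=0.5, seed=1)
truth = cd.simulate_study(config)

print(f"samples: {len(truth.cohort)}  "
      f"({truth.cohort['karyotype'].value_counts().to_dict()})")
print(f"circRNAs: {len(truth.circ_features)} by region class:")
print(truth.circ_features["region_class"].value_counts().to_string())

par = truth.true_effects.query("kind == 'circ' and region_class == 'PAR1'")
print(f"\nplanted PAR1 circRNA log2FC (47,XXY vs 46,XY): "
      f"{par['47XXY_vs_46XY'].iloc[0]:.3f}")
print("= alpha * log2(3/2): the mRNA dosage effect scaled by the circRNA "
      "attenuation factor 0.5")
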