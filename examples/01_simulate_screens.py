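"""Generate the synthetic primary and secondary screens with ground truth.

The primary screen mimics a genome-wide miRNA-mimic perturbation read out
by RPPA: 879 miRNAs x 127 antibodies, four signature-carrying clusters
plus one null cluster.  The secondary screens re-profile a 154-miRNA
subset in three cell lines whose phosphoprotein blocks follow planted
sparse Gaussian graphical models.
"""

import collections

from mirscreen.simulate import (
    SimulationConfig,
    simulate_primary_screen,
    simulate_secondary_screens,
)

config = SimulationConfig(seed=1)
primary, labels = simulate_primary_screen(config)
print(f"primary screen: {primary.shape[0]} rows x {primary.shape[1]} proteins "
      f"({config.n_controls} rows are non-targeting controls)")
sizes = collections.Counter(labels[labels > 0])
print("planted cluster sizes:", dict(sorted(sizes.items())))
# cluster 3 is the null cluster: miRNAs with only minor protein effects

secondary = simulate_secondary_screens(config, seed=1)
print(f"secondary screens: {len(secondary.screens)} cell lines, "
      f"{secondary.screens[0].shape[0]} miRNAs x "
      f"{secondary.screens[0].shape[1]} proteins, "
      f"{len(secondary.shared_protein_ids)} proteins shared with screen 1")
print(f"planted regulator edges (miRNA -> phosphoprotein): "
      f"{len(secondary.regulators)}")
for line, ggm in sorted(secondary.ggms.items()):
    print(f"  cell line {line}: {len(ggm.support)} planted network edges")
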