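"""Build miRNA -> phosphoprotein regulator networks and pathway scores.

A regulator edge needs the same up/down call in at least two of the
three cell lines; miRNAs with fewer than two targets are dropped.  A
miRNA enters a pathway network when it changes at least half of the
pathway's measured proteins in the primary screen.
"""

from mirscreen.preprocess import discretize, normalize
from mirscreen.regulators import build_phospho_regulators, pathway_fractions
from mirscreen.screens import is_phospho
from mirscreen.simulate import (
    SimulationConfig,
    default_pathways,
    simulate_primary_screen,
    simulate_secondary_screens,
)

config = SimulationConfig(seed=1)
secondary = simulate_secondary_screens(config, flip_prob=0.05, seed=1)
discs = [discretize(s) for s in secondary.screens]
phospho = [p for p in secondary.screens[0].protein_ids if is_phospho(p)]

up, down = build_phospho_regulators(discs, phospho, min_lines=2, min_targets=2)
print(f"up-regulator network: {len(up.edges)} edges, "
      f"{up.edges['mirna'].nunique()} miRNAs")
print(f"down-regulator network: {len(down.edges)} edges, "
      f"{down.edges['mirna'].nunique()} miRNAs")
truth = set(zip(secondary.regulators.mirna, secondary.regulators.protein))
found = set(zip(up.edges.mirna, up.edges.protein)) | set(
    zip(down.edges.mirna, down.edges.protein))
print(f"planted regulator edges recovered: {len(truth & found)}/{len(truth)}")

primary, labels = simulate_primary_screen(config)
controls = [m for m in primary.mirna_ids if m.startswith("NTC-")]
disc1 = discretize(normalize(primary, controls, drop_controls=True))
reg = pathway_fractions(disc1, default_pathways(), threshold=0.5)
inc = reg.included()
print("\nmiRNAs regulating at least half of each pathway:")
for pathway, group in inc.groupby("pathway"):
    print(f"  {pathway}: {len(group)} miRNAs "
          f"(max regulated fraction {group['fraction'].max():.2f})")
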