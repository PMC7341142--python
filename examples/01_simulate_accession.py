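"""Simulate a landrace/DH accession pair and write a plain-text fixture.

One accession is generated under the three-stage sampling scheme: 23
landrace diploids genotyped from the ancestral population, a surviving
pool of 100 DH lines (10% of sites carry a recessive viability cost of
s = 0.5 on lines homozygous for the alternative allele), and 58 of those
lines genotyped.
"""

from pathlib import Path

import numpy as np

from dhdrift import SimulationConfig, simulate_accession, write_fixture_set

cfg = SimulationConfig(
    n_sites=2000,
    n_lr_individuals=23,
    n_dh_lines=58,
    n_H=100,
    selection_s=0.5,
    selected_fraction=0.1,
    seed=1,
)
sim = simulate_accession(cfg)

out = Path("scratch/example_accession")
paths = write_fixture_set(sim, out)

selected = sim.s > 0
f_lr = sim.lr.dosages.mean() / 2
f_dh = sim.dh.dosages.mean() / 2
print(f"sites simulated:            {cfg.n_sites} ({selected.sum()} under selection)")
print(f"mean LR allele frequency:   {f_lr:.4f}")
print(f"mean DH allele frequency:   {f_dh:.4f}")
print(f"mean DH freq, neutral:      {sim.dh.dosages[:, ~selected].mean() / 2:.4f}")
print(f"mean DH freq, selected:     {sim.dh.dosages[:, selected].mean() / 2:.4f}")
print(f"fixture written to:         {out}/")
# Selection against homozygous carriers depresses the DH frequency at
# selected sites relative to the neutral sites and to the landrace, which
# is exactly the signal the outlier tests are built to detect.
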