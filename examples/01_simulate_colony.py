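"""Generate a synthetic colony-season and write its four CSV tables.

The colony emulates a breeding season of ~21 herring-gull pairs next to an
abundant small-gull prey base: individual diets drawn around a known
population diet, territory searches on a fixed schedule, carcass counts with
seasonal availability peaks, and attack/aggression event streams.
"""

import json
from pathlib import Path

from gulldiet import simulate_colony, write_tables
from gulldiet.simulate import paper_regime

outdir = Path("scratch/example_colony")
result = simulate_colony(paper_regime("gull_island_2009", seed=1))
write_tables(result.tables, outdir)
(outdir / "ground_truth.json").write_text(json.dumps(result.ground_truth, indent=2))

gt = result.ground_truth
print(f"pairs:              {len(gt['p_pairs'])}")
print(f"pellets collected:  {len(result.tables['pellets'])}")
print(f"search occasions:   {len(gt['search_julians'])}")
print(f"population diet q:  {[round(x, 3) for x in gt['q_true']]}")
print(f"expected impact:    {gt['expected_impact']} kills/pair/day")
print(f"tables written to:  {outdir}/")
# q is the latent population diet every pair's own diet is drawn around;
# the expected impact is the mean daily kill rate the carcass model encodes.
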