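"""Generate the study-scale synthetic registry scenario.

Writes the tract geography (GeoJSON), the stratified count grid with
expected-count offsets, raw visit records (with injected repeat visits for
the deduplication step), and the ground-truth spatial fields to
results/scenario/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import logging

from vetcatch.pipeline import cmd_simulate
from vetcatch.synthdata import ScenarioConfig

logging.basicConfig(level=logging.INFO, format="%(message)s")

OUT = Path(__file__).resolve().parents[1] / "results" / "scenario"
SEED = 1


def main():
    cfg = ScenarioConfig(seed=SEED)
    graph, counts, truth = cmd_simulate(cfg, OUT, write_records=True)
    print(f"wrote scenario to {OUT}")
    print(f"  tracts: {len(graph.tracts)} (20 x 20 grid, queen contiguity)")
    print(f"  strata: {len(counts)} (tract x species x period)")
    print(f"  visits: {counts.y_visits.sum()}, cancer: {counts.y_cancer.sum()}")
    print(f"  true catchment (nu > 0): {len(truth.true_ca)} tracts")


if __name__ == "__main__":
    main()
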