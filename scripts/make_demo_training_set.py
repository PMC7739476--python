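#!/usr/bin/env python
"""Regenerate the packaged demo training table.

The table shipped at ``src/dnmindel/data/demo_training_set.synthetic.tsv``
is assembled from one small simulated trio (it is fully synthetic, as the
filename notes) and exists so users can try ``train``/``predict`` without
first running a simulation.
"""

from pathlib import Path

from dnmindel.experiments import build_training_table
from dnmindel.simulate import SimConfig, run_simulation

OUT = Path(__file__).resolve().parents[1] / "src" / "dnmindel" / "data"

CONFIG = SimConfig(
    ref_length=80_000, n_homopolymers=20, n_strs=20, n_inherited_indels=50,
    n_denovo_indels=8, n_artifact_sites=20, coverage=25, seed=404,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sim = run_simulation(CONFIG)
    table = build_training_table(sim, seed=404)
    table.write(
        str(OUT / "demo_training_set.synthetic.tsv"),
        str(OUT / "demo_training_set.synthetic.json"),
    )
    print(f"wrote {len(table.df)} rows, composition {table.composition}")


if __name__ == "__main__":
    main()
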