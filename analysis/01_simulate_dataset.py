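#!/usr/bin/env python
"""Emit a small simulated dataset to disk (FASTA, per-cell SAM, truth tables).

A reduced-scale mixed tumor/leukocyte experiment is written under
results/dataset/ so the file-level CLI flows (quantify, variants,
coverage-model) have something to chew on. The full-scale experiments used
by the other drivers are simulated in memory instead of being written out.
"""

from pathlib import Path

from ctcseq import demo
from ctcseq.simulate import SimConfig, emit_dataset, sample_cells

OUT = Path(__file__).resolve().parents[1] / "results" / "dataset"


def main():
    panel = demo.demo_panel()
    clone_a, clone_b = demo.tumor_clones(panel, shared_expression=False)
    populations = [clone_a, clone_b, demo.wbc_population()]
    cfg = SimConfig(
        n_cells_per_population={"clone_a": 4, "clone_b": 4, "wbc": 2},
        fragments_per_cell=5000,
        master_seed=11,
    )
    cells = sample_cells(populations, cfg, panel)
    manifest = emit_dataset(cells, panel, populations, cfg, OUT)
    print(f"wrote {len(manifest['files'])} files for {manifest['n_cells']} cells to {OUT}")
    print("cells:", ", ".join(manifest["cells"]))


if __name__ == "__main__":
    main()
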