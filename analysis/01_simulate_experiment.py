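#!/usr/bin/env python
"""Simulate the multi-heart uptake imaging experiment.

Renders a sham group (4 hearts, EV-free perfusate, faint 488 signal) and two
EV-treated groups (3 hearts each): wild-type EVs with no real uptake and
targeted NeonGreen2 EVs with strong, relatively even cytoplasmic signal.
Two-channel field TIFFs and ground-truth labels go to scratch/experiment/ (they
are intermediate binaries); the manifest is the handoff to 02.
"""

from pathlib import Path

from evuptake.pipeline import RunConfig, run_pipeline

CONFIG = RunConfig(
    output_dir=Path("scratch/experiment"),
    seed=20,
    simulation={"n_live_cells": 4, "n_dead_cells": 1},
    design={
        "treatments": [
            {"label": "sham", "neon_mean": 5.0, "heterogeneity_amplitude": 0.30},
            {"label": "wt_ev", "neon_mean": 5.5, "heterogeneity_amplitude": 0.30},
            {"label": "targeted_ev", "neon_mean": 40.0, "heterogeneity_amplitude": 0.12},
        ],
        "hearts_per_group": {"sham": 4, "wt_ev": 3, "targeted_ev": 3},
        "cells_per_heart": 16,
        "heart_sd": 2.0,
        "cell_sd": 4.0,
    },
)

if __name__ == "__main__":
    report = run_pipeline(CONFIG, stages=("simulate",))
    print(f"wrote {report['stages']['simulate']['n_fields']} fields to {CONFIG.output_dir}")
    print("next: python analysis/02_segment_and_measure.py")
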