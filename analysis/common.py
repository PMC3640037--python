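"""Shared plumbing for the numbered analysis drivers.

Each driver rebuilds the synthetic cohort deterministically from the seed
(the generator is cheap and byte-stable), so the scripts can be run in any
order; the cohort tables land in ``results/cohort/``.
"""

import argparse
from pathlib import Path

from gcresponse.io import config_hash
from gcresponse.pipeline import PipelineConfig, stage_simulate
from gcresponse.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parents[1]


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--results", type=Path, default=ROOT / "results")
    return parser.parse_args()


def load_cohort(args):
    cfg = PipelineConfig(sim=SimulationConfig(seed=args.seed))
    cohort_dir = args.results / "cohort"
    cohort_dir.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg.to_dict())
    data = stage_simulate(cfg, cohort_dir, h)
    return cfg, data, h
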