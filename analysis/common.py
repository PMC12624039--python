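"""Shared argument handling for the numbered analysis drivers.

Each driver is a thin narrative wrapper over one pipeline stage: all
computation lives in the ``qmpdecomp`` package, and every driver reads its
predecessors' tables from the shared run directory (default ``results/run``).
"""

from __future__ import annotations

import argparse
import logging

from qmpdecomp.io import RunConfig


def run_config(description: str) -> RunConfig:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--outdir", default="results/run", help="shared run directory")
    parser.add_argument("--seed", type=int, default=0, help="master seed")
    parser.add_argument("--n-trees", type=int, default=1000, help="random-forest size")
    parser.add_argument("--n-eval-runs", type=int, default=100, help="forest reseeds per evaluation")
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    return RunConfig(outdir=args.outdir, seed=args.seed, n_trees=args.n_trees, n_eval_runs=args.n_eval_runs)
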