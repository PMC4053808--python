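"""Shared plumbing for the numbered analysis scripts.

Each script reads its inputs from and writes its outputs to a results
directory (default ``results/`` next to this file) so the scripts can be
run in order: 01 simulates the dataset, later steps consume the text
artifacts it wrote.
"""

from __future__ import annotations

import argparse
import json
import os

import pandas as pd

HERE = os.path.dirname(os.path.abspath(__file__))
DEFAULT_RESULTS = os.path.join(HERE, "..", "results")


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--results-dir", default=DEFAULT_RESULTS)
    return parser.parse_args()


def results_path(args: argparse.Namespace, name: str) -> str:
    os.makedirs(args.results_dir, exist_ok=True)
    return os.path.join(args.results_dir, name)


def write_tsv(df: pd.DataFrame, args: argparse.Namespace, name: str) -> None:
    df.to_csv(results_path(args, name), sep="\t", index=False)
    print(f"wrote {name}: {len(df)} rows")


def read_tsv(args: argparse.Namespace, name: str) -> pd.DataFrame:
    return pd.read_csv(results_path(args, name), sep="\t")


def write_json(obj, args: argparse.Namespace, name: str) -> None:
    with open(results_path(args, name), "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
    print(f"wrote {name}")
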