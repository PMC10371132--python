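"""Flat-file emission of search results and per-strategy metrics.

Solutions go to TSV (one row per strategy, semicolon-joined sorted reaction
sets), run metadata to JSON.  Floats are printed with 6 significant digits;
consumers should compare numerically, not by string.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import pandas as pd

from .search import SearchResult, SolutionRecord

SOLUTION_COLUMNS = [
    "level",
    "reactions",
    "genes",
    "co_knocked",
    "growth",
    "product_min",
    "product_max",
    "mode",
]


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def solutions_to_frame(records: Iterable[SolutionRecord]) -> pd.DataFrame:
    rows = [
        {
            "level": rec.level,
            "reactions": ";".join(rec.reactions),
            "genes": ";".join(rec.genes),
            "co_knocked": ";".join(rec.co_knocked),
            "growth": _fmt(rec.growth),
            "product_min": _fmt(rec.product_min),
            "product_max": _fmt(rec.product_max),
            "mode": rec.qualifying_mode,
        }
        for rec in records
    ]
    return pd.DataFrame(rows, columns=SOLUTION_COLUMNS)


def write_solutions_tsv(records: Iterable[SolutionRecord], path: Union[str, Path]) -> None:
    solutions_to_frame(records).to_csv(path, sep="\t", index=False)


def read_solutions_tsv(path: Union[str, Path]) -> List[SolutionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(
            SolutionRecord(
                reactions=tuple(row["reactions"].split(";")) if row["reactions"] else (),
                level=int(row["level"]),
                growth=float(row["growth"]),
                product_min=float(row["product_min"]),
                product_max=float(row["product_max"]),
                qualifying_mode=row["mode"],
                genes=tuple(row["genes"].split(";")) if row["genes"] else (),
                co_knocked=tuple(row["co_knocked"].split(";")) if row["co_knocked"] else (),
            )
        )
    return records


def run_metadata(result: SearchResult, extra: dict | None = None) -> dict:
    meta = {
        "thresholds": asdict(result.thresholds),
        "node_count": result.node_count,
        "lp_count": result.lp_count,
        "fva_lp_count": result.fva_lp_count,
        "n_solutions": len(result.solutions),
        "n_raw_solutions": len(result.raw_solutions),
        "config": {
            **{k: (sorted(v) if isinstance(v, frozenset) else v) for k, v in asdict(result.config).items()},
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        meta.update(extra)
    return meta


def write_metadata_json(result: SearchResult, path: Union[str, Path], extra: dict | None = None) -> None:
    Path(path).write_text(json.dumps(run_metadata(result, extra), indent=2) + "\n")
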