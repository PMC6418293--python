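"""Report writers: per-run relevance tables, the wide five-set relevance
layout, enrichment long/wide tables, and config echoes.

Writers are pure functions of their inputs: writing the same objects twice
produces byte-identical files.  Human-facing wide tables print scores and
p-values to 2 decimals (blank cells where a set did not score a target);
long-format companions keep full precision.
"""

from __future__ import annotations

import json
import os
from typing import Mapping

from .enrichment import EnrichmentTable
from .prioritize import RelevanceTable

__all__ = [
    "write_relevance_table",
    "write_wide_relevance",
    "write_enrichment_reports",
    "write_config_echo",
]


def write_relevance_table(rt: RelevanceTable, path: str) -> None:
    rt.to_tsv(path)


def write_wide_relevance(
    tables: Mapping[str, RelevanceTable],
    path: str,
    reference: str | None = None,
) -> None:
    """Write the multi-seed-set wide relevance table.

    One row per target in the union of all tables; two columns (relevance,
    p-value) per seed set; rows ordered by the reference set's ranking (first
    set by default), targets unseen by the reference appended by best
    relevance.  Cells are blank for (target, set) pairs without a score.
    """
    names = list(tables)
    if not names:
        raise ValueError("no relevance tables given")
    reference = reference if reference is not None else names[0]
    if reference not in tables:
        raise ValueError(f"reference set {reference!r} not among tables")
    per_set: dict[str, dict[str, tuple[float, float]]] = {}
    target_name: dict[str, str] = {}
    for name, rt in tables.items():
        col = {}
        for row in rt.table.itertuples(index=False):
            col[row.target_id] = (row.relevance_score, row.p_value)
            target_name[row.target_id] = row.target_name
        per_set[name] = col
    ref_order = [
        row.target_id
        for row in tables[reference].table.itertuples(index=False)
    ]
    rest = sorted(
        set(target_name) - set(ref_order),
        key=lambda t: (
            -max(per_set[n][t][0] for n in names if t in per_set[n]),
            t,
        ),
    )
    with open(path, "w", encoding="utf-8") as fh:
        header = ["target_id", "target_name"]
        for name in names:
            header += [f"{name}_relevance", f"{name}_p_value"]
        fh.write("\t".join(header) + "\n")
        for t in ref_order + rest:
            cells = [t, target_name[t]]
            for name in names:
                if t in per_set[name]:
                    rel, p = per_set[name][t]
                    cells += [f"{rel:.2f}", f"{p:.2f}"]
                else:
                    cells += ["", ""]
            fh.write("\t".join(cells) + "\n")


def write_enrichment_reports(et: EnrichmentTable, out_dir: str) -> None:
    """Write the long per-algorithm table and the contrasts × sets wide table
    of BH-adjusted combined p-values."""
    os.makedirs(out_dir, exist_ok=True)
    et.to_tsv(os.path.join(out_dir, "enrichment_long.tsv"))
    wide = et.wide()
    with open(
        os.path.join(out_dir, "enrichment_wide.tsv"), "w", encoding="utf-8"
    ) as fh:
        cols = list(wide.columns)
        fh.write("\t".join(["contrast"] + cols) + "\n")
        for contrast, row in wide.iterrows():
            cells = [str(contrast)] + [f"{row[c]:.3g}" for c in cols]
            fh.write("\t".join(cells) + "\n")


def write_config_echo(config: Mapping, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dict(config), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
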