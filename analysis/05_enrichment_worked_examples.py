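#!/usr/bin/env python
"""Recompute the worked-example molecular-function enrichment tables.

For every reference row (two top-25 target lists against a universe of
15,288 GO-annotated genes) the hypergeometric tail p is recomputed from
(r, R, n, N) and compared with the reported value at 3 significant figures.
Writes results/worked_example_enrichment.tsv.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from mclprio.enrichment_stats import hypergeom_tail
from mclprio.worked_examples import CONTROL_TARGET_ENRICHMENT, NOVEL_TARGET_ENRICHMENT

ROOT = Path(__file__).resolve().parents[1]


def sig3(x: float) -> float:
    exp = math.floor(math.log10(abs(x)))
    return round(x / 10**exp, 2) * 10**exp


def main() -> None:
    rows = []
    for list_name, table in (
        ("control", CONTROL_TARGET_ENRICHMENT),
        ("novel", NOVEL_TARGET_ENRICHMENT),
    ):
        for row in table:
            p = hypergeom_tail(row.r, row.R, row.n, row.N)
            rows.append(
                {
                    "list": list_name,
                    "term": row.term,
                    "r": row.r,
                    "R": row.R,
                    "n": row.n,
                    "N": row.N,
                    "reported_p": row.p,
                    "recomputed_p": p,
                    "match_3sf": sig3(p) == sig3(row.p),
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(
        ROOT / "results" / "worked_example_enrichment.tsv",
        sep="\t",
        index=False,
        float_format="%.3e",
    )
    n_match = int(table["match_3sf"].sum())
    print(f"{n_match} of {len(table)} reported enrichment p-values reproduced at 3 s.f.")
    worst = (table["recomputed_p"] / table["reported_p"]).apply(lambda x: abs(math.log10(x))).max()
    print(f"largest |log10(recomputed/reported)|: {worst:.4f}")


if __name__ == "__main__":
    main()
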