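"""Readers and writers for the plain-text interchange formats.

Trait tables are TSV with header ``label<TAB>gcn``; clade maps TSV
``label<TAB>clade``; community tables TSV with OTUs as rows and samples as
columns; predictions TSV carry the integer PMF as a JSON column.  Numeric
output uses 12 significant digits so diffs are stable.
"""

from __future__ import annotations

import pandas as pd

from .correction import CommunityTable, CorrectedAbundanceTable

__all__ = [
    "read_traits", "write_traits", "read_clade_map", "read_counts",
    "write_counts", "write_predictions", "read_predictions",
    "write_corrected", "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.12g"


def read_traits(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    if not {"label", "gcn"} <= set(df.columns):
        raise ValueError("trait TSV must have columns 'label' and 'gcn'")
    if df["label"].duplicated().any():
        dup = df.loc[df["label"].duplicated(), "label"].iloc[0]
        raise ValueError(f"duplicate label in trait table: {dup!r}")
    vals = df["gcn"].astype(float)
    if (vals < 1).any():
        raise ValueError("copy numbers must be >= 1")
    return dict(zip(df["label"], vals.astype(int)))


def write_traits(traits: dict[str, float], path) -> None:
    pd.DataFrame({"label": list(traits), "gcn": [int(v) for v in traits.values()]}) \
        .to_csv(path, sep="\t", index=False)


def read_clade_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"label", "clade"} <= set(df.columns):
        raise ValueError("clade map TSV must have columns 'label' and 'clade'")
    return dict(zip(df["label"], df["clade"]))


def read_counts(path) -> CommunityTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CommunityTable(df)


def write_counts(table: CommunityTable, path) -> None:
    table.counts.to_csv(path, sep="\t")


def write_predictions(predictions, path) -> None:
    rows = []
    for p in predictions:
        rows.append({
            "query": p.query,
            "gcn": p.point_estimate,
            "confidence": p.confidence,
            "reliable": p.reliable,
            "adjusted_nstd": p.adjusted_nstd,
            "group": p.group,
            "pmf_json": p.pmf.to_json(),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format=FLOAT_FORMAT)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_corrected(table: CorrectedAbundanceTable, path) -> None:
    long = []
    for sample in table.point.columns:
        for otu in table.point.index:
            long.append({
                "otu": otu, "sample": sample,
                "point": table.point.at[otu, sample],
                "ci_low": table.ci_low.at[otu, sample],
                "ci_high": table.ci_high.at[otu, sample],
            })
    pd.DataFrame(long).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
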