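"""File interfaces: phenotype TSVs, BOLD array containers, parcellations.

BOLD time series are stored one ``.npy`` file per participant next to a
tab-separated manifest (``participant_id``, ``file``, ``n_parcels``,
``n_volumes``), which keeps the arrays portable and memory-mappable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .caps import ParcelTimeSeries

__all__ = [
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_bold_dataset",
    "read_bold_dataset",
    "write_parcellation_tsv",
    "read_parcellation_tsv",
]


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bold_dataset(
    series: list[ParcelTimeSeries], out_dir, manifest_name: str = "manifest.tsv"
) -> Path:
    """Write one .npy per participant plus an index manifest; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in series:
        fname = f"{s.participant_id}_bold.npy"
        np.save(out / fname, s.data)
        rows.append(
            {
                "participant_id": s.participant_id,
                "file": fname,
                "n_parcels": s.n_parcels,
                "n_volumes": s.n_volumes,
                "parcellation": s.parcellation,
                "tr": s.tr,
            }
        )
    manifest = out / manifest_name
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_bold_dataset(manifest_path) -> list[ParcelTimeSeries]:
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t")
    series = []
    for _, row in table.iterrows():
        arr = np.load(manifest_path.parent / row["file"])
        series.append(
            ParcelTimeSeries(
                participant_id=str(row["participant_id"]),
                data=arr,
                parcellation=str(row.get("parcellation", "unspecified")),
                tr=float(row.get("tr", 2.5)),
            )
        )
    return series


def write_parcellation_tsv(network_labels, path) -> None:
    pd.DataFrame(
        {"parcel_id": range(1, len(network_labels) + 1), "network": list(network_labels)}
    ).to_csv(path, sep="\t", index=False)


def read_parcellation_tsv(path) -> tuple[str, ...]:
    table = pd.read_csv(path, sep="\t")
    return tuple(table.sort_values("parcel_id")["network"].astype(str))
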