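"""Plain-text readers and writers for the pipeline's tabular artefacts.

Beta matrices travel as TSV (rows = CpGs, first column ``cpg_id``), sample
sheets and fraction tables as CSV, reference panels and delta-beta records as
TSV, index models and run summaries as JSON.
"""

from __future__ import annotations

import json

import pandas as pd

from .deconv import ReferencePanel


def write_beta_tsv(beta: pd.DataFrame, path) -> None:
    beta.rename_axis("cpg_id").to_csv(path, sep="\t")


def read_beta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cpg_id")


def write_sheet_csv(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def read_sheet_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fractions_csv(fractions: pd.DataFrame, path) -> None:
    fractions.rename_axis("sample_id").to_csv(path)


def read_fractions_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_panel_tsv(panel: ReferencePanel, path) -> None:
    wide = panel.centroid.copy()
    wide.insert(0, "cell_type", panel.markers.set_index("cpg_id")["cell_type"].reindex(wide.index))
    wide.rename_axis("cpg_id").to_csv(path, sep="\t")


def read_panel_tsv(path) -> ReferencePanel:
    wide = pd.read_csv(path, sep="\t", index_col="cpg_id")
    markers = wide[["cell_type"]].reset_index()
    centroid = wide.drop(columns="cell_type")
    return ReferencePanel(markers=markers, centroid=centroid, thresholds={})


def write_records_tsv(records: pd.DataFrame, path) -> None:
    records.rename_axis("cpg_id").to_csv(path, sep="\t")


def read_records_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cpg_id")


def read_blocklist(path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    try:
        import numpy as np

        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serialisable: {type(o)}")
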