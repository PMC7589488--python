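"""TSV serialization shared by all modules.

All interchange files are tab-separated UTF-8 text with the label
column first: mutation-type label for counts and signatures, signature
name for exposures. The signature reader also accepts the COSMIC
30-signature probability file layout (extra annotation columns are
dropped). Counts are written without scientific notation. Every CLI run
additionally writes a small JSON metadata record (package version,
configuration, seed) next to its outputs.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Any

import pandas as pd

LABEL_COLUMN = "mutation_type"

# Annotation columns of the published COSMIC probability file that are
# not signature columns.
_COSMIC_META_COLUMNS = {
    "Substitution Type",
    "Trinucleotide",
    "Somatic Mutation Type",
}


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label=LABEL_COLUMN, float_format="%.10f"
              if df.to_numpy().dtype.kind == "f" else None)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = LABEL_COLUMN
    return df


def write_signatures(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label=LABEL_COLUMN, float_format="%.10g")


def read_signatures(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    label_col = df.columns[0]
    if "Somatic Mutation Type" in df.columns:
        # COSMIC layout: the mutation-type label lives in its own column
        label_col = "Somatic Mutation Type"
    df = df.set_index(label_col)
    df = df.drop(columns=[c for c in df.columns if c in _COSMIC_META_COLUMNS], errors="ignore")
    df = df.dropna(axis=1, how="all")
    df.index.name = LABEL_COLUMN
    return df.astype(float)


def write_exposures(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="signature", float_format="%.10g")


def read_exposures(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "signature"
    return df


def write_silhouettes(assignments, widths, path: str | Path) -> None:
    pd.DataFrame(
        {"solution": range(len(widths)), "cluster": assignments, "width": widths}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_run_metadata(path: str | Path, config: dict[str, Any]) -> None:
    """Machine-readable record of a run: version, platform, parameters."""
    from . import __version__

    record = {
        "package": "mutsig",
        "version": __version__,
        "python": platform.python_version(),
        "config": config,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
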