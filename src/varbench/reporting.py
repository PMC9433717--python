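"""Report serialization and run provenance.

All tabular reports are TSV with ``.`` as the undefined-value marker and a
fixed, locale-independent float format, so identical inputs produce
byte-identical files.  Every output directory receives exactly one
``manifest.json`` recording the command, config/input digests and the seed.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger("varbench")

UNDEFINED_MARKER = "."
FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path) -> Path:
    """Write a report table as TSV (``.`` for undefined, stable floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(
        path, sep="\t", index=False, na_rep=UNDEFINED_MARKER,
        float_format=FLOAT_FORMAT,
    )
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[UNDEFINED_MARKER])


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(
    out_dir,
    command: str,
    config: dict,
    input_paths=(),
    seed: int | None = None,
    registry_version: str = "builtin",
) -> Path:
    """Write the run manifest for an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_digest": sha256_obj(config),
        "input_digests": [
            {"path": str(p), "sha256": sha256_file(p)} for p in input_paths
        ],
        "seed": seed,
        "tool_registry_version": registry_version,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def plot_ranking(table, path) -> None:
    """Optional ranked bar chart; failures never affect pipeline status."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = table.rows
        fig, ax = plt.subplots(figsize=(7, max(2, 0.25 * len(df))))
        ax.barh(df["tool"][::-1], df[table.ranking_metric][::-1])
        ax.set_xlabel(table.ranking_metric)
        ax.set_title(table.dataset)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
    except Exception as err:  # plots are cosmetic, never fatal
        logger.warning("plotting failed (%s); continuing", err)
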