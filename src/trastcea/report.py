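"""Deterministic report writing: TSV tables, run manifests, optional plots.

Numeric formatting convention: VND amounts as integers, US$ rounded to whole
dollars, probabilities and utilities to four decimals, life years and QALYs
to six.  Every output set is accompanied by a JSON manifest (written last)
recording the inputs, seed and package version needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

__all__ = ["RunManifest", "write_tables", "write_manifest", "format_frame"]


@dataclass
class RunManifest:
    """Provenance of one analysis run, sufficient to reproduce it."""

    subcommand: str
    config: str
    lifetable: str
    seed: int
    iterations: int
    out_dir: str
    version: str
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()


def _fmt_value(col: str, v):
    if pd.isna(v):
        return ""
    name = col.lower()
    if name.endswith("_vnd") or name == "vnd" or name.endswith("_vnd_per_qaly"):
        return str(int(round(v)))
    if name.endswith("_usd") or name == "usd":
        return str(int(round(v)))
    if name.startswith(("p_", "prob")) or name in ("qx",):
        return f"{v:.4f}"
    if isinstance(v, float):
        return f"{v:.6g}" if abs(v) >= 1e-4 or v == 0 else f"{v:.6e}"
    return str(v)


def format_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the reporting number formats column-wise, returning strings."""
    out = {}
    for col in df.columns:
        series = df[col]
        if series.dtype.kind in "if":
            out[col] = [_fmt_value(col, v) for v in series]
        else:
            out[col] = series.astype(str).where(~series.isna(), "")
    return pd.DataFrame(out)


def write_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                 formatted: bool = True) -> list[Path]:
    """Write each table as ``<name>.tsv`` with a header row.

    Empty tables raise before anything is written, so a failed run leaves no
    partial output set.
    """
    out_dir = Path(out_dir)
    for name, df in tables.items():
        if len(df) == 0:
            raise ValueError(f"table {name!r} is empty; nothing written")
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        if formatted:
            format_frame(df).to_csv(path, sep="\t", index=False)
        else:
            # %.17g guarantees float64 values survive the text round trip
            df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        paths.append(path)
    return paths


def write_manifest(manifest: RunManifest, out_dir: str | Path) -> Path:
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# optional plots (matplotlib imported lazily, Agg backend)
# ---------------------------------------------------------------------------

def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_psa_scatter(draws: pd.DataFrame, wtp_thresholds, path: str | Path) -> None:
    """Incremental cost-effectiveness plane with willingness-to-pay lines."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(draws["d_qaly"], draws["d_cost"] / 1e6, s=4, alpha=0.3)
    qmax = float(draws["d_qaly"].max()) * 1.05
    for lam, style in zip(wtp_thresholds, ("-", "--")):
        ax.plot([0, qmax], [0, lam * qmax / 1e6], "k", linestyle=style,
                label=f"{lam/1e6:.0f}M VND/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (million VND)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ceac(ceac_df: pd.DataFrame, path: str | Path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    lam = ceac_df["lambda_vnd_per_qaly"] / 1e6
    ax.plot(lam, ceac_df["p_trastuzumab"], label="trastuzumab + chemo")
    ax.plot(lam, ceac_df["p_chemo"], label="chemo alone")
    ax.set_xlabel("Willingness-to-pay (million VND per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tornado(tornado_df: pd.DataFrame, base_icer: float, path: str | Path,
                 top: int = 15) -> None:
    plt = _plt()
    df = tornado_df[tornado_df["valid"]].head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = sorted((row["icer_low_vnd"], row["icer_high_vnd"]))
        ax.barh(i, (hi - lo) / 1e6, left=lo / 1e6, height=0.6)
    ax.axvline(base_icer / 1e6, color="k", lw=1)
    ax.set_yticks(range(len(df)), df["parameter"])
    ax.set_xlabel("ICER (million VND per QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
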