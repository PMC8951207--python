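"""File formats and run configuration.

Recordings travel as a delimited channels x samples matrix plus a YAML
sidecar (sampling rate, channel labels, optional neighbour table), or as EDF
when ``mne`` is installed.  Metabolite tables, scores, PLI matrices, and
topology curves are plain TSV.  :class:`RunConfig` holds the pipeline's fixed
constants and round-trips losslessly through YAML.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .metabolomics import MetaboliteTable
from .montage import Montage, CANONICAL_20, _DEFAULT_NEIGHBORS
from .preprocess import Band, DEFAULT_BANDS, Recording
from .connectivity import PLIMatrix
from .network import TopologyCurve

__all__ = [
    "RunConfig", "read_recording", "write_recording",
    "read_metabolite_table", "write_metabolite_table",
    "read_scores", "write_scores", "write_pli_matrix", "read_pli_matrix",
    "write_topology_curves", "read_topology_curves",
]


# ----------------------------------------------------------------------------
# Recordings
# ----------------------------------------------------------------------------

def write_recording(recording: Recording, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (label + samples per row) and ``<prefix>.yaml``."""
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".tsv")
    side_path = prefix.with_suffix(".yaml")
    with open(data_path, "w") as fh:
        for lab, row in zip(recording.montage.labels, recording.data):
            fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    sidecar = {
        "fs": float(recording.fs),
        "labels": list(recording.montage.labels),
        "neighbors": {k: sorted(v) for k, v in recording.montage.neighbors.items()},
        "units": "uV",
    }
    side_path.write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return data_path, side_path


def _montage_from_sidecar(sidecar: dict) -> Montage:
    labels = [str(x) for x in sidecar["labels"]]
    neighbors = sidecar.get("neighbors")
    if neighbors is None:
        # fall back to the canonical adjacency restricted to these labels
        neighbors = {
            lab: tuple(n for n in _DEFAULT_NEIGHBORS.get(lab, ()) if n in labels)
            for lab in labels
        }
    return Montage(labels, neighbors)


def read_recording(path: str | Path, *, require: Sequence[str] | None = None) -> Recording:
    """Read a recording from ``.tsv``+``.yaml`` (or ``.edf`` via mne).

    Values are normalized to microvolts.  With ``require`` set, missing
    channels raise an explicit error naming them.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path)
    else:
        side_path = path.with_suffix(".yaml")
        if not side_path.exists():
            raise FileNotFoundError(f"missing sidecar {side_path} (needs fs and labels)")
        sidecar = yaml.safe_load(side_path.read_text())
        if "fs" not in sidecar:
            raise ValueError(f"sidecar {side_path} missing sampling rate 'fs'")
        labels = []
        rows = []
        with open(path.with_suffix(".tsv")) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                labels.append(parts[0])
                rows.append(np.array(parts[1:], dtype=np.float64))
        if labels != [str(x) for x in sidecar["labels"]]:
            raise ValueError("channel labels in data file and sidecar disagree")
        rec = Recording(np.vstack(rows), float(sidecar["fs"]), _montage_from_sidecar(sidecar))
    if require is not None:
        missing = [ch for ch in require if ch not in rec.montage.labels]
        if missing:
            raise ValueError(f"recording {path} is missing required channels: {missing}")
    return rec


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = [ch.upper() for ch in raw.ch_names]
    data = raw.get_data() * 1e6  # volts -> microvolts (per-channel gains applied by mne)
    neighbors = {
        lab: tuple(n for n in _DEFAULT_NEIGHBORS.get(lab, ()) if n in labels)
        for lab in labels
    }
    return Recording(data, float(raw.info["sfreq"]), Montage(labels, neighbors))


# ----------------------------------------------------------------------------
# Tables
# ----------------------------------------------------------------------------

def write_metabolite_table(table: MetaboliteTable, path: str | Path) -> Path:
    """TSV: first column sample ID, second group label, then feature columns."""
    path = Path(path)
    out = table.intensities.copy()
    out.insert(0, "group", table.groups)
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_metabolite_table(path: str | Path, *, group_order=None) -> MetaboliteTable:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    groups = df.pop("group")
    return MetaboliteTable(df, groups, group_order=group_order)


def write_scores(scores: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    frame = scores.rename("score").rename_axis("sample").reset_index()
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_scores(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return pd.Series(frame["score"].to_numpy(), index=frame["sample"], name="score")


def write_pli_matrix(matrix: PLIMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_pli_matrix(path: str | Path, *, band: Band | None = None) -> PLIMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return PLIMatrix(df.to_numpy(), tuple(df.columns), band=band)


def write_topology_curves(curves: Sequence[TopologyCurve], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.concat([c.to_frame() for c in curves], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_topology_curves(path: str | Path) -> list[TopologyCurve]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    curves = []
    for (subject, band), sub in frame.groupby(["subject", "band"], sort=False, dropna=False):
        if pd.isna(band):
            band = None
        wide = sub.pivot(index="sparsity", columns="metric", values="value").sort_index()
        frag = (
            sub.drop_duplicates("sparsity").set_index("sparsity")["fragmented"]
            .sort_index().to_numpy(dtype=bool)
        )
        curves.append(TopologyCurve(
            wide.index.to_numpy(), wide["lp"].to_numpy(), wide["cc"].to_numpy(),
            wide["eglobal"].to_numpy(), wide["elocal"].to_numpy(), frag,
            band=band, subject=subject,
        ))
    return curves


# ----------------------------------------------------------------------------
# Run configuration
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """All fixed constants of the analysis pipeline.

    Defaults are the study constants: 0.5-45 Hz band-pass with 50 Hz notch,
    2-s epochs, average reference, 512 Hz, +/-80 uV rejection, Laplacian,
    sparsity grid 0.05-0.40 step 0.01, alpha = 0.05 with BH-FDR per
    band x metric, NBS primary t = 2.0.
    """

    bands: dict = field(default_factory=lambda: {
        name: [b.f_low, b.f_high] for name, b in DEFAULT_BANDS.items()
    })
    broadband: tuple = (0.5, 45.0)
    notch_hz: float = 50.0
    epoch_len_s: float = 2.0
    target_fs: float = 512.0
    reject_uv: float = 80.0
    apply_laplacian: bool = True
    edge_trim: float = 0.1
    sparsity_min: float = 0.05
    sparsity_max: float = 0.40
    sparsity_step: float = 0.01
    alpha: float = 0.05
    fdr_family: str = "band_metric"
    nbs_primary_t: float = 2.0
    nbs_n_perm: int = 1000
    metab_log_transform: bool = True
    metab_scale: str = "unit-variance"
    metab_n_components: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.sparsity_min < self.sparsity_max < 1):
            raise ValueError("invalid sparsity range")
        if self.sparsity_step <= 0 or self.epoch_len_s <= 0 or self.target_fs <= 0:
            raise ValueError("invalid numeric setting")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def band_objects(self) -> dict[str, Band]:
        return {name: Band(name, float(lo), float(hi)) for name, (lo, hi) in self.bands.items()}

    def sparsity_grid(self) -> np.ndarray:
        n = int(round((self.sparsity_max - self.sparsity_min) / self.sparsity_step)) + 1
        return np.round(self.sparsity_min + self.sparsity_step * np.arange(n), 10)

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["broadband"] = list(d["broadband"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src: str | Path) -> "RunConfig":
        text = Path(src).read_text() if isinstance(src, Path) or "\n" not in str(src) else str(src)
        d = yaml.safe_load(text)
        d["broadband"] = tuple(d["broadband"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
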