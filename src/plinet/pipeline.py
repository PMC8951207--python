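"""End-to-end pipeline: preprocess -> PLI -> networks -> statistics.

`run_pipeline` ties the stages together for a cohort of recordings (plus an
optional metabolite table and depression scores), writing delimited result
tables stamped with the config hash and seed, and logging per-stage subject
attrition (recordings whose epochs were all rejected are dropped and named).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .connectivity import PLIMatrix, pli_matrix
from .correlate import CorrelationMap, metabolite_topology_scan, score_metabolite_correlation
from .groupstats import AveragedComparison, NbsResult, average_significant, compare_topology, nbs_test
from .metabolomics import MetaboliteTable, ScreenResult, univariate_screen
from .montage import CANONICAL_20
from .network import METRICS, TopologyCurve, topology_curves
from .preprocess import Band, Recording, preprocess_recording

log = logging.getLogger("plinet")

__all__ = ["BandResult", "PipelineResult", "subject_pli", "run_pipeline"]


def subject_pli(recording: Recording, band: Band, config: pio.RunConfig) -> PLIMatrix:
    """Preprocess one recording for one band and compute its PLI matrix."""
    epochs = preprocess_recording(
        recording, band,
        broadband=tuple(config.broadband),
        notch_freq=config.notch_hz,
        epoch_len_s=config.epoch_len_s,
        target_fs=config.target_fs,
        reject_uv=config.reject_uv,
        apply_laplacian=config.apply_laplacian,
    )
    if epochs.n_epochs == 0:
        raise ValueError("all epochs rejected")
    channels = [ch for ch in CANONICAL_20 if ch in recording.montage.labels]
    missing = sorted(set(CANONICAL_20) - set(channels))
    if missing:
        raise ValueError(f"recording lacks canonical channels: {missing}")
    return pli_matrix(epochs, channels=CANONICAL_20, edge_trim=config.edge_trim)


@dataclass
class BandResult:
    band: str
    pli: dict[str, PLIMatrix]
    curves: list[TopologyCurve]
    comparison: pd.DataFrame | None = None
    averaged: dict[str, AveragedComparison] = field(default_factory=dict)
    nbs: NbsResult | None = None


@dataclass
class PipelineResult:
    config: pio.RunConfig
    bands: dict[str, BandResult]
    labels: dict[str, str]
    attrition: pd.DataFrame
    screen: ScreenResult | None = None
    scan: CorrelationMap | None = None
    score_correlation: pd.DataFrame | None = None
    out_dir: Path | None = None


def _input_checksums(recordings: Mapping[str, Recording]) -> dict[str, str]:
    import hashlib
    out = {}
    for sid, rec in recordings.items():
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(rec.data).tobytes())
        h.update(str(rec.fs).encode())
        h.update(",".join(rec.montage.labels).encode())
        out[sid] = h.hexdigest()[:16]
    return out


def run_pipeline(
    config: pio.RunConfig,
    recordings: Mapping[str, Recording],
    labels: Mapping[str, str],
    *,
    table: MetaboliteTable | None = None,
    scores: pd.Series | None = None,
    bands: Sequence[str] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a labelled cohort of recordings.

    ``labels`` maps subject ID to one of exactly two group names; the first
    label encountered (by subject order) is the case group.  ``bands``
    restricts analysis to a subset of the configured bands.  Identical config
    and inputs give identical outputs.
    """
    band_objs = config.band_objects()
    use = list(bands) if bands is not None else list(band_objs)
    unknown = [b for b in use if b not in band_objs]
    if unknown:
        raise KeyError(f"bands not in config: {unknown}")
    subjects = list(recordings)
    group_names = list(dict.fromkeys(labels[s] for s in subjects))
    if len(group_names) != 2:
        raise ValueError(f"need exactly two group labels, got {group_names}")
    grid = config.sparsity_grid()

    attrition_rows = []
    band_results: dict[str, BandResult] = {}
    for bname in use:
        band = band_objs[bname]
        pli: dict[str, PLIMatrix] = {}
        curves: list[TopologyCurve] = []
        dropped: list[str] = []
        for sid in subjects:
            try:
                m = subject_pli(recordings[sid], band, config)
            except ValueError as exc:
                log.warning("band %s subject %s dropped: %s", bname, sid, exc)
                dropped.append(sid)
                continue
            pli[sid] = m
            curves.append(topology_curves(m, grid, band=bname, subject=sid))
        attrition_rows.append((bname, len(subjects), len(subjects) - len(dropped), dropped))
        res = BandResult(bname, pli, curves)
        kept = [s for s in subjects if s in pli]
        ca = [c for c in curves if labels[c.subject] == group_names[0]]
        cb = [c for c in curves if labels[c.subject] == group_names[1]]
        if len(ca) >= 2 and len(cb) >= 2:
            res.comparison = compare_topology(ca, cb, fdr_family=config.fdr_family)
            for metric in METRICS:
                avg = average_significant(ca, cb, metric, alpha=config.alpha,
                                          comparison=res.comparison)
                if avg is not None:
                    res.averaged[metric] = avg
            res.nbs = nbs_test(
                [pli[s] for s in kept if labels[s] == group_names[0]],
                [pli[s] for s in kept if labels[s] == group_names[1]],
                primary_t=config.nbs_primary_t,
                n_perm=config.nbs_n_perm,
                seed=config.seed,
            )
        band_results[bname] = res

    attrition = pd.DataFrame(attrition_rows, columns=["band", "n_input", "n_kept", "dropped"])

    screen = scan = score_corr = None
    if table is not None:
        screen = univariate_screen(
            table,
            n_components=config.metab_n_components,
            log_transform=config.metab_log_transform,
            scale=config.metab_scale,
        )
        selected = screen.selected
        if len(selected) > 0:
            feats = table.intensities.loc[:, selected]
            frames = []
            arg_frames = []
            for bname, res in band_results.items():
                if res.curves:
                    cm = metabolite_topology_scan(feats, res.curves)
                    frames.append(cm.frame)
                    arg_frames.append(cm.argmax)
            if frames:
                scan = CorrelationMap(pd.concat(frames, ignore_index=True),
                                      pd.concat(arg_frames, ignore_index=True))
            if scores is not None:
                score_corr = score_metabolite_correlation(scores, feats)
    else:
        log.info("no metabolite table supplied; metabolomics stages skipped")

    result = PipelineResult(config, band_results, dict(labels), attrition,
                            screen, scan, score_corr)
    if out_dir is not None:
        result.out_dir = Path(out_dir)
        _write_results(result, _input_checksums(recordings))
    return result


def _write_results(result: PipelineResult, checksums: dict[str, str] | None = None) -> None:
    import json
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    stamp = f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n"
    cfg.to_yaml(out / "config.yaml")
    (out / "provenance.json").write_text(json.dumps(
        {"config_hash": cfg.config_hash(), "seed": cfg.seed,
         "input_checksums": checksums or {}}, indent=2) + "\n")

    def _write(frame: pd.DataFrame, name: str, index=False):
        path = out / name
        with open(path, "w") as fh:
            fh.write(stamp)
            frame.to_csv(fh, sep="\t", index=index, float_format="%.10g")

    result.attrition.to_csv(out / "attrition.tsv", sep="\t", index=False)
    for bname, res in result.bands.items():
        bdir = out / bname
        bdir.mkdir(exist_ok=True)
        for sid, m in res.pli.items():
            pio.write_pli_matrix(m, bdir / f"pli_{sid}.tsv")
        if res.curves:
            pio.write_topology_curves(res.curves, bdir / "topology.tsv")
        if res.comparison is not None:
            _write(res.comparison, f"{bname}/comparison.tsv")
        if res.averaged:
            rows = [
                (bname, m, ";".join(f"{s:g}" for s in a.significant_sparsities),
                 a.t, a.df, a.p, a.cohens_d)
                for m, a in res.averaged.items()
            ]
            _write(pd.DataFrame(rows, columns=["band", "metric", "sparsities",
                                               "t", "df", "p", "cohens_d"]),
                   f"{bname}/averaged.tsv")
        if res.nbs is not None:
            rows = [
                (i, len(comp), res.nbs.component_p[i],
                 ";".join(f"{a}-{b}" for a, b in comp))
                for i, comp in enumerate(res.nbs.components)
            ]
            _write(pd.DataFrame(rows, columns=["component", "n_edges", "p", "edges"]),
                   f"{bname}/nbs.tsv")
    if result.screen is not None:
        _write(result.screen.frame.rename_axis("feature"), "screen.tsv", index=True)
    if result.scan is not None:
        _write(result.scan.frame, "correlation_scan.tsv")
        _write(result.scan.argmax, "correlation_argmax.tsv")
    if result.score_correlation is not None:
        _write(result.score_correlation.reset_index(), "score_correlation.tsv")
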