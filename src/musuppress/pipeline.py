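"""Seeded end-to-end pipeline runs.

Stage order: preprocessing (DC removal, average reference, trim,
concatenate) -> Welch PSD -> mu band power -> sensor MSI + inferential
battery; then, when a source model is supplied, wMNE projection ->
per-vertex MSI -> paired before/after contrast -> cluster sign-flip
permutation test.  Every default in PipelineConfig reproduces the study's
printed constants.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import io as mio
from .clusterperm import ClusterResult, paired_differences, permutation_test
from .core import ConfigurationError, Recording, SourceModel
from .inverse import build_wmne, project_segment
from .msi import (
    MSITable,
    median_split,
    msi_table_from_powers,
    msi_ttest_zero,
    rm_anova,
)
from .preprocessing import preprocess_condition
from .spectral import band_power, welch_psd

log = logging.getLogger("musuppress")


@dataclass
class PipelineConfig:
    """All pipeline constants; defaults equal the study's printed values."""

    trim_action: float = 2.0
    trim_rest: float = 10.0
    clip_seconds: float = 24.0
    welch_window: float = 2.0
    welch_overlap: float = 0.5
    welch_taper: str = "hamming"
    mu_band: tuple[float, float] = (8.0, 13.0)
    baseline_condition: str = "balls"
    electrodes: tuple[str, ...] | None = ("C3", "C4", "Cz")
    lambda2: float | str = "auto"
    depth_gamma: float = 0.5
    snr: float = 3.0
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        """Deterministic per-stage seed split from the global seed."""
        digest = hashlib.sha256(stage.encode()).digest()
        return np.random.SeedSequence([self.seed, int.from_bytes(digest[:4], "big")])


@dataclass
class PipelineResult:
    sensor_msi: MSITable
    ttests: pd.DataFrame
    anova: pd.DataFrame | None
    split: pd.Series | None
    source_msi: MSITable | None
    clusters: dict[str, ClusterResult]
    config_hash: str

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.sensor_msi.to_csv(os.path.join(out_dir, "sensor_msi.csv"))
        self.ttests.to_csv(os.path.join(out_dir, "ttests.csv"), index=False)
        if self.anova is not None:
            self.anova.to_csv(os.path.join(out_dir, "anova.csv"), index=False)
        if self.split is not None:
            self.split.to_csv(os.path.join(out_dir, "median_split.csv"))
        if self.source_msi is not None:
            self.source_msi.to_csv(os.path.join(out_dir, "source_msi.csv"))
        for cond, res in self.clusters.items():
            res.to_frame().to_csv(
                os.path.join(out_dir, f"clusters_{cond}.csv"), index=False
            )
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump({"config_hash": self.config_hash}, fh)


def _iter_recordings(recordings, manifest: mio.StudyManifest | None):
    if recordings is not None:
        for rec in recordings:
            role = "rest" if rec.condition.startswith("rest") else "action"
            yield rec, role
    else:
        for row in manifest.table.itertuples():
            rec = mio.read_recording(manifest.resolve(row))
            rec.subject, rec.session = str(row.subject), str(row.session)
            rec.condition = str(row.condition)
            yield rec, str(row.role)


def _electrode_set(cfg: PipelineConfig, ch_names: list[str]):
    if cfg.electrodes is None:
        return [n for n in ch_names if mio.is_eeg_channel(n)]
    missing = [e for e in cfg.electrodes if e not in ch_names]
    if missing:
        raise ConfigurationError(
            f"electrodes {missing} not present in the data; set "
            "PipelineConfig.electrodes to a valid set or None for all channels"
        )
    return list(cfg.electrodes)


def run_pipeline(
    recordings: list[Recording] | None = None,
    manifest: mio.StudyManifest | None = None,
    config: PipelineConfig | None = None,
    model: SourceModel | None = None,
) -> PipelineResult:
    """Run the full analysis on a study.

    Provide either in-memory recordings or a manifest of files.  The
    source stage (wMNE + cluster permutation) runs only when a source
    model is supplied.  Deterministic given config.seed.
    """
    if (recordings is None) == (manifest is None):
        raise ConfigurationError("provide exactly one of recordings/manifest")
    cfg = config or PipelineConfig()

    kernel = build_wmne(model, cfg.lambda2, cfg.depth_gamma, cfg.snr) if model else None
    sensor_powers: dict[tuple[str, str, str], object] = {}
    source_powers: dict[tuple[str, str, str], object] = {}
    ch_names: list[str] = []
    lo, hi = cfg.mu_band
    for rec, role in _iter_recordings(recordings, manifest):
        ch_names = rec.ch_names
        trim = cfg.trim_rest if role == "rest" else cfg.trim_action
        clip = None if role == "rest" else cfg.clip_seconds
        seg = preprocess_condition(rec, clip, trim)
        key = (rec.subject, rec.session, rec.condition)
        spec = welch_psd(seg, cfg.welch_window, cfg.welch_overlap, cfg.welch_taper)
        sensor_powers[key] = band_power(spec, lo, hi)
        if kernel is not None:
            sspec = welch_psd(project_segment(seg, kernel),
                              cfg.welch_window, cfg.welch_overlap, cfg.welch_taper)
            source_powers[key] = band_power(sspec, lo, hi)
        log.info("processed %s", key)

    if not any(k[2] == cfg.baseline_condition for k in sensor_powers):
        raise ConfigurationError(
            f"baseline condition {cfg.baseline_condition!r} missing from study"
        )
    sensor_msi = msi_table_from_powers(
        {k: v for k, v in sensor_powers.items() if not k[2].startswith("rest")},
        ch_names, cfg.baseline_condition,
    )
    electrodes = _electrode_set(cfg, ch_names)

    sessions = sorted(sensor_msi.table.session.unique())
    conditions = sorted(sensor_msi.table.condition.unique())
    rows = []
    for sess in sessions:
        for cond in conditions:
            means = sensor_msi.subject_means(cond, sess, electrodes)
            res = msi_ttest_zero(means)
            rows.append({"session": sess, "condition": cond, "n": res.n,
                         "mean": res.mean, "sd": res.sd, "t": res.t,
                         "df": res.df, "p": res.p, "d": res.d,
                         "ci_lo": res.ci[0], "ci_hi": res.ci[1]})
    ttests = pd.DataFrame(rows)

    anova = None
    n_subjects = sensor_msi.table.subject.nunique()
    if len(sessions) >= 2 and len(conditions) >= 2 and n_subjects >= 2:
        sub = sensor_msi.table[sensor_msi.table.location.isin(electrodes)]
        anova = rm_anova(sub, ["session", "condition", "location"])

    split = None
    if n_subjects >= 2:
        first = sessions[0]
        per_subject = (
            sensor_msi.table[
                (sensor_msi.table.session == first)
                & sensor_msi.table.location.isin(electrodes)
            ].groupby("subject")["msi"].mean()
        )
        split = median_split(per_subject)

    source_msi = None
    clusters: dict[str, ClusterResult] = {}
    if kernel is not None:
        vertex_names = [f"v{i:03d}" for i in range(model.n_vertices)]
        source_msi = msi_table_from_powers(
            {k: v for k, v in source_powers.items() if not k[2].startswith("rest")},
            vertex_names, cfg.baseline_condition,
        )
        if len(sessions) >= 2:
            pre, post = sessions[0], sessions[-1]
            perm_seed = cfg.stage_seed("cluster_perm")
            for cond in conditions:
                t = source_msi.table
                a = MSITable(t[(t.session == pre) & (t.condition == cond)],
                             cfg.baseline_condition)
                b = MSITable(t[(t.session == post) & (t.condition == cond)],
                             cfg.baseline_condition)
                diffs = paired_differences(a, b)
                child = np.random.default_rng(perm_seed.spawn(1)[0]).integers(2**31)
                clusters[cond] = permutation_test(
                    diffs, model.adjacency, cfg.n_perm, cfg.cluster_alpha,
                    seed=int(child),
                )
    return PipelineResult(
        sensor_msi=sensor_msi, ttests=ttests, anova=anova, split=split,
        source_msi=source_msi, clusters=clusters, config_hash=cfg.config_hash(),
    )
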