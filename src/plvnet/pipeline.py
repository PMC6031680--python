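"""Stage-wise pipeline: simulate -> preprocess -> localize -> connect ->
metrics -> stats -> report.

Every stage reads its inputs from, and writes its outputs to, a run
directory, so any single stage can be re-run from persisted intermediates
and reproduce the downstream results of a monolithic run exactly.  All
randomness derives from one root seed through fixed spawn keys, and all
artifacts are written with fixed numeric formats, so a fixed-seed run is
byte-for-byte reproducible.

Layout of a run directory::

    cohort.csv            subject metadata + covariates
    epochs/sub-XXX.npz    simulated (sensor- or source-space) epochs
    preproc/sub-XXX.npz   filtered, artifact-free, condition-selected epochs
    preprocess_log.csv    per-subject epoch bookkeeping
    gain.csv              synthetic lead field (localize stage)
    connectivity/*.csv    one square PLV matrix per subject x band + index
    metrics_global.csv    long-format global indices
    metrics_nodal.csv     long-format nodal strength / clustering
    stats_global.csv      omnibus ANCOVA per band x index (+ post-hoc)
    stats_nodal.csv       per-node clustering ANCOVA
    correlations.csv      partial correlations with trauma measures
    summary.json          thresholds and headline counts
    manifest.json         parameters actually used, per stage
    report.md             human-readable tables
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn_mod
from . import graph_metrics as gm
from . import group_stats as gs
from . import preprocess as pp
from . import source_inverse as si
from . import synthetic_data as sd

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"
STAGES = ("simulate", "preprocess", "localize", "connect", "metrics", "stats")


@dataclass
class PipelineConfig:
    """Everything a run needs, in one validated bundle."""

    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    bands: tuple[conn_mod.BandDefinition, ...] = conn_mod.DEFAULT_BANDS
    plv_window_ms: tuple[float, float] = conn_mod.DEFAULT_PLV_WINDOW_MS
    sensor_band: tuple[float, float] = (0.1, 55.0)  # broad-band pre-filter
    artifact_threshold_uv: float = 75.0
    localize: bool = True  # sensor round trip through the minimum-norm inverse
    n_sensors: int = 32
    snr: float = 3.0
    lam: float | None = None  # None -> default_lambda(gain, snr)
    alpha: float = 0.05
    global_family: int = 16  # 4 indices x 4 bands
    nodal_family: int | None = None  # None -> node count
    correlation_family: int = 60
    covariates: tuple[str, ...] = ("sai", "tai", "bdi", "caars_total")
    plv_convention: str = "across_trials"

    def validate(self) -> None:
        self.sim.validate()
        lo, hi = self.plv_window_ms
        if not (self.sim.epoch_tmin_ms <= lo < hi <= self.sim.epoch_tmax_ms):
            raise ValueError(
                f"PLV window {self.plv_window_ms} ms outside epoch span "
                f"[{self.sim.epoch_tmin_ms}, {self.sim.epoch_tmax_ms}] ms"
            )
        nyq = self.sim.sample_rate / 2.0
        for band in self.bands:
            if band.f_hi >= nyq:
                raise ValueError(
                    f"band {band.name} exceeds the Nyquist rate {nyq} Hz"
                )
        if self.artifact_threshold_uv <= 0:
            raise ValueError("artifact threshold must be positive")
        for fam in (self.global_family, self.correlation_family):
            if fam < 1:
                raise ValueError("test family sizes must be >= 1")
        if self.localize and self.n_sensors < 1:
            raise ValueError("need at least one sensor")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [asdict(b) for b in self.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = sd.SimConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["sim"].items()
            })
        if "bands" in d:
            d["bands"] = tuple(conn_mod.BandDefinition(**b)
                               for b in d["bands"])
        for key in ("plv_window_ms", "sensor_band", "covariates"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _save_epochs(path: Path, epochs: pp.EpochSet) -> None:
    np.savez(path, data=epochs.data, sample_rate=epochs.sample_rate,
             tmin_ms=epochs.tmin_ms,
             conditions=epochs.conditions.astype(str),
             correct=epochs.correct)


def _load_epochs(path: Path) -> pp.EpochSet:
    with np.load(path, allow_pickle=False) as z:
        return pp.EpochSet(
            data=z["data"],
            sample_rate=float(z["sample_rate"]),
            tmin_ms=float(z["tmin_ms"]),
            conditions=z["conditions"].astype(object),
            correct=z["correct"],
        )


class PipelineRun:
    """One seeded run over a run directory.

    Stage methods can be called individually (they load persisted inputs)
    or all at once through :meth:`run_all`.
    """

    def __init__(self, config: PipelineConfig, outdir: str | Path,
                 scratch_dir: str | Path | None = None) -> None:
        config.validate()
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.scratch = Path(scratch_dir) if scratch_dir else self.outdir
        self.scratch.mkdir(parents=True, exist_ok=True)
        self._manifest_path = self.outdir / "manifest.json"

    # -- helpers -----------------------------------------------------------

    def _epoch_dir(self, name: str) -> Path:
        d = self.scratch / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _record_stage(self, stage: str, params: dict) -> None:
        manifest = {}
        if self._manifest_path.exists():
            manifest = json.loads(self._manifest_path.read_text())
        manifest.setdefault("config", self.config.to_dict())
        manifest.setdefault("stages", {})[stage] = params
        self._manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )

    def _subject_ids(self) -> list[str]:
        cohort = pd.read_csv(self.outdir / "cohort.csv")
        return list(cohort["subject_id"])

    def _fail(self, stage: str, subject: str | None, exc: Exception):
        where = f"stage {stage!r}" + (f", subject {subject}" if subject else "")
        raise RuntimeError(f"pipeline aborted at {where}: {exc}") from exc

    # -- stages ------------------------------------------------------------

    def simulate(self) -> None:
        """Generate the cohort: metadata table plus per-subject epochs."""
        cfg = self.config
        records, epochs = sd.generate_cohort(cfg.sim)
        sd.cohort_to_frame(records).to_csv(
            self.outdir / "cohort.csv", index=False, float_format=FLOAT_FMT)
        edir = self._epoch_dir("epochs")
        if cfg.localize:
            gain = si.make_synthetic_gain(
                cfg.n_sensors, cfg.sim.n_nodes,
                seed=int(np.random.SeedSequence(
                    cfg.sim.seed, spawn_key=(7,)).generate_state(1)[0]
                    % (2**31)),
            )
            np.savetxt(self.outdir / "gain.csv", gain.matrix,
                       delimiter=",", fmt="%.17g")
            np.savetxt(self.outdir / "gain_coords.csv",
                       gain.source_coordinates, delimiter=",", fmt="%.17g")
            noise_seeds = np.random.SeedSequence(
                cfg.sim.seed, spawn_key=(8,)).spawn(len(records))
            for rec, ep, nseed in zip(records, epochs, noise_seeds):
                sensor = sd.project_to_sensors(
                    ep, gain, sensor_noise_sd=cfg.sim.amplitude_noise_sd,
                    seed=np.random.default_rng(nseed))
                _save_epochs(edir / f"{rec.subject_id}.npz", sensor)
        else:
            for rec, ep in zip(records, epochs):
                _save_epochs(edir / f"{rec.subject_id}.npz", ep)
        self._record_stage("simulate", {
            "n_subjects": len(records), "localize_input": cfg.localize,
            "seed": cfg.sim.seed,
        })

    def preprocess(self) -> None:
        """Broad-band filter, reject +/- threshold epochs, keep correct NoGo."""
        cfg = self.config
        edir = self._epoch_dir("epochs")
        pdir = self._epoch_dir("preproc")
        rows = []
        for sid in self._subject_ids():
            try:
                epochs = _load_epochs(edir / f"{sid}.npz")
                f_lo, f_hi = cfg.sensor_band
                f_hi = min(f_hi, 0.499 * epochs.sample_rate)
                epochs = pp.bandpass_filter(epochs, f_lo, f_hi)
                epochs, log = pp.reject_artifacts(
                    epochs, cfg.artifact_threshold_uv)
                kept = epochs.n_trials
                try:
                    epochs = pp.select_condition(epochs, pp.NOGO,
                                                 correct_only=True)
                    n_nogo = epochs.n_trials
                except ValueError:
                    n_nogo = 0
                rows.append({"subject_id": sid, "n_total": log.n_total,
                             "n_rejected": log.n_removed, "n_clean": kept,
                             "n_nogo_correct": n_nogo})
                if n_nogo:
                    _save_epochs(pdir / f"{sid}.npz", epochs)
            except Exception as exc:  # noqa: BLE001 - abort with context
                self._fail("preprocess", sid, exc)
        pd.DataFrame(rows).to_csv(self.outdir / "preprocess_log.csv",
                                  index=False)
        self._record_stage("preprocess", {
            "band": list(cfg.sensor_band),
            "threshold_uv": cfg.artifact_threshold_uv,
            "condition": pp.NOGO,
        })

    def localize(self) -> None:
        """Minimum-norm inverse back to node space (if enabled)."""
        cfg = self.config
        if not cfg.localize:
            self._record_stage("localize", {"enabled": False})
            return
        gain = si.GainMatrix(
            matrix=np.loadtxt(self.outdir / "gain.csv", delimiter=","),
            source_coordinates=np.loadtxt(self.outdir / "gain_coords.csv",
                                          delimiter=","),
        )
        lam = cfg.lam if cfg.lam is not None else si.default_lambda(
            gain, cfg.snr)
        inv = si.minimum_norm_inverse(gain, lam)
        pdir = self._epoch_dir("preproc")
        ldir = self._epoch_dir("source")
        for sid in self._subject_ids():
            path = pdir / f"{sid}.npz"
            if not path.exists():
                continue
            try:
                _save_epochs(ldir / f"{sid}.npz",
                             si.apply_inverse(_load_epochs(path), inv))
            except Exception as exc:  # noqa: BLE001
                self._fail("localize", sid, exc)
        self._record_stage("localize", {"lambda": lam, "snr": cfg.snr,
                                        "n_sensors": cfg.n_sensors})

    def _source_dir(self) -> Path:
        return self._epoch_dir("source" if self.config.localize else "preproc")

    def connect(self) -> None:
        """Per-subject, per-band PLV adjacency matrices."""
        cfg = self.config
        srcdir = self._source_dir()
        cdir = self.outdir / "connectivity"
        cdir.mkdir(parents=True, exist_ok=True)
        subject_epochs = {}
        for sid in self._subject_ids():
            path = srcdir / f"{sid}.npz"
            if path.exists():
                subject_epochs[sid] = _load_epochs(path)
        conn = conn_mod.cohort_connectivity(
            subject_epochs, bands=cfg.bands, window_ms=cfg.plv_window_ms,
            condition=None,  # selection already happened in preprocess
            convention=cfg.plv_convention,
        )
        for sid, per_band in conn.items():
            for band, matrix in per_band.items():
                conn_mod.save_matrix(matrix, cdir / f"{sid}_{band}.csv")
        conn_mod.connectivity_index(conn).to_csv(
            cdir / "index.csv", index=False)
        self._record_stage("connect", {
            "bands": [b.name for b in cfg.bands],
            "window_ms": list(cfg.plv_window_ms),
            "convention": cfg.plv_convention,
            "n_subjects_used": len(conn),
        })

    def _load_connectivity(self) -> dict:
        cdir = self.outdir / "connectivity"
        index = pd.read_csv(cdir / "index.csv")
        conn: dict[str, dict[str, conn_mod.ConnectivityMatrix]] = {}
        for _, row in index.iterrows():
            sid, band = row["subject_id"], row["band"]
            conn.setdefault(sid, {})[band] = conn_mod.load_matrix(
                cdir / f"{sid}_{band}.csv", band=band, subject_id=sid)
        return conn

    def metrics(self) -> None:
        """Global and nodal weighted network indices."""
        conn = self._load_connectivity()
        gtab, ntab = gm.metrics_tables(conn)
        gtab.to_csv(self.outdir / "metrics_global.csv", index=False,
                    float_format=FLOAT_FMT)
        ntab.to_csv(self.outdir / "metrics_nodal.csv", index=False,
                    float_format=FLOAT_FMT)
        self._record_stage("metrics", {"n_networks": int(len(gtab) // 4)})

    def stats(self) -> None:
        """Covariate-adjusted group statistics with Bonferroni control."""
        cfg = self.config
        cohort = pd.read_csv(self.outdir / "cohort.csv")
        gtab = pd.read_csv(self.outdir / "metrics_global.csv")
        ntab = pd.read_csv(self.outdir / "metrics_nodal.csv")
        covs = list(cfg.covariates)
        meta = cohort[["subject_id", "group_label", *covs]]

        alpha_global = gs.bonferroni_threshold(cfg.alpha, cfg.global_family)
        merged = gtab.merge(meta, on="subject_id")
        grows = []
        for (band, index), sub in merged.groupby(["band", "index"],
                                                 sort=True):
            res = gs.ancova_group_test(
                sub["value"], sub["group_label"], sub[covs],
                index=index, band=band, adjusted_alpha=alpha_global)
            row = {"band": band, "index": index, "F": res.f_stat,
                   "df_effect": res.df_effect, "df_error": res.df_error,
                   "p": res.p_value, "partial_eta_sq": res.partial_eta_sq,
                   "adjusted_alpha": alpha_global,
                   "significant": bool(res.p_value < alpha_global)}
            if res.p_value < alpha_global:
                pw = gs.posthoc_pairwise(sub["value"], sub["group_label"],
                                         sub[covs])
                for (g1, g2), comp in pw.items():
                    row[f"p_{g1}_vs_{g2}"] = comp.p_adjusted
                    row[f"diff_{g1}_vs_{g2}"] = comp.diff
            grows.append(row)
        stats_global = pd.DataFrame(grows)
        stats_global.to_csv(self.outdir / "stats_global.csv", index=False,
                            float_format=FLOAT_FMT)

        n_nodes = int(ntab["node"].max()) + 1 if len(ntab) else 0
        nodal_family = cfg.nodal_family or max(n_nodes, 1)
        alpha_nodal = gs.bonferroni_threshold(cfg.alpha, nodal_family)
        ncl = ntab[ntab["index"] == "clustering"].merge(meta, on="subject_id")
        nrows = []
        for (band, node), sub in ncl.groupby(["band", "node"], sort=True):
            res = gs.ancova_group_test(
                sub["value"], sub["group_label"], sub[covs],
                index="clustering", band=band, adjusted_alpha=alpha_nodal)
            nrows.append({"band": band, "node": node, "F": res.f_stat,
                          "p": res.p_value,
                          "partial_eta_sq": res.partial_eta_sq,
                          "adjusted_alpha": alpha_nodal,
                          "significant": bool(res.p_value < alpha_nodal)})
        stats_nodal = pd.DataFrame(nrows)
        stats_nodal.to_csv(self.outdir / "stats_nodal.csv", index=False,
                           float_format=FLOAT_FMT)

        # partial correlations of nodal clustering with trauma measures,
        # at the nodes flagged by the nodal ANCOVA (all nodes if none)
        alpha_corr = gs.bonferroni_threshold(cfg.alpha,
                                             cfg.correlation_family)
        trauma_measures = ["ctq_total", *sd._SUBSCALE_NAMES]
        flagged = stats_nodal[stats_nodal["significant"]]
        targets = (flagged if len(flagged)
                   else stats_nodal)[["band", "node"]]
        crows = []
        cmeta = cohort[["subject_id", *covs, *trauma_measures]]
        for _, trg in targets.iterrows():
            sub = ncl[(ncl["band"] == trg["band"])
                      & (ncl["node"] == trg["node"])]
            sub = sub.merge(cmeta[["subject_id", *trauma_measures]],
                            on="subject_id")
            for measure in trauma_measures:
                res = gs.partial_correlation(
                    sub[measure], sub["value"], sub[covs].to_numpy(),
                    x_name=measure, y_name=f"clustering_node{trg['node']}",
                    band=trg["band"])
                crows.append({
                    "band": trg["band"], "node": trg["node"],
                    "measure": measure, "r_partial": res.r_partial,
                    "p": res.p_value, "n": res.n,
                    "adjusted_alpha": alpha_corr,
                    "significant": bool(res.p_value < alpha_corr)})
        pd.DataFrame(crows).to_csv(self.outdir / "correlations.csv",
                                   index=False, float_format=FLOAT_FMT)

        summary = {
            "alpha": cfg.alpha,
            "adjusted_alpha_global": alpha_global,
            "adjusted_alpha_nodal": alpha_nodal,
            "adjusted_alpha_correlation": alpha_corr,
            "n_global_significant": int(stats_global["significant"].sum()),
            "n_nodal_significant": int(stats_nodal["significant"].sum())
            if len(stats_nodal) else 0,
            "covariates": covs,
        }
        (self.outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        self._record_stage("stats", summary)

    def run_all(self) -> None:
        self.simulate()
        self.preprocess()
        self.localize()
        self.connect()
        self.metrics()
        self.stats()

    # -- reporting ---------------------------------------------------------

    def render_report(self) -> str:
        """Markdown summary: group mean +/- SD tables, tests, correlations."""
        out = self.outdir
        required = ["cohort.csv", "metrics_global.csv", "stats_global.csv"]
        missing = [f for f in required if not (out / f).exists()]
        if missing:
            raise ValueError(f"result bundle incomplete; missing {missing}")
        cohort = pd.read_csv(out / "cohort.csv")
        gtab = pd.read_csv(out / "metrics_global.csv").merge(
            cohort[["subject_id", "group_label"]], on="subject_id")
        stats_global = pd.read_csv(out / "stats_global.csv")

        lines = ["# Pipeline report", ""]
        sizes = cohort["group_label"].value_counts()
        lines.append("## Cohort")
        lines.append("")
        lines.append("| group | n | CTQ total (mean +/- SD) |")
        lines.append("|---|---|---|")
        for g in ("low", "middle", "high"):
            if g not in sizes:
                continue
            sub = cohort[cohort["group_label"] == g]["ctq_total"]
            lines.append(f"| {g} | {len(sub)} | "
                         f"{sub.mean():.2f} +/- {sub.std(ddof=1):.2f} |")
        lines.append("")

        lines.append("## Global network indices (mean +/- SD by group)")
        lines.append("")
        header = "| band | index | " + " | ".join(
            g for g in ("low", "middle", "high") if g in set(sizes.index)
        ) + " | p | partial eta^2 |"
        lines.append(header)
        lines.append("|" + "---|" * (header.count("|") - 1))
        for (band, index), sub in gtab.groupby(["band", "index"],
                                               sort=True):
            cells = []
            for g in ("low", "middle", "high"):
                if g not in set(sizes.index):
                    continue
                v = sub[sub["group_label"] == g]["value"]
                cells.append(f"{v.mean():.4f} +/- {v.std(ddof=1):.4f}")
            row = stats_global[(stats_global["band"] == band)
                               & (stats_global["index"] == index)]
            p = float(row["p"].iloc[0])
            eta = float(row["partial_eta_sq"].iloc[0])
            mark = "**" if bool(row["significant"].iloc[0]) else ""
            lines.append(f"| {band} | {index} | " + " | ".join(cells)
                         + f" | {mark}{p:.4g}{mark} | {eta:.3f} |")
        lines.append("")

        nodal_path = out / "stats_nodal.csv"
        if nodal_path.exists():
            stats_nodal = pd.read_csv(nodal_path)
            sig = stats_nodal[stats_nodal["significant"]]
            lines.append("## Nodal clustering")
            lines.append("")
            if len(sig):
                lines.append("| band | node | F | p |")
                lines.append("|---|---|---|---|")
                for _, r in sig.iterrows():
                    lines.append(f"| {r['band']} | {int(r['node'])} | "
                                 f"{r['F']:.2f} | {r['p']:.3g} |")
            else:
                lines.append("No node survives the nodal Bonferroni "
                             "threshold.")
            lines.append("")
        else:
            lines.append("_Nodal stage outputs absent; section omitted._")
            logger.info("nodal stats missing; report section omitted")
            lines.append("")

        corr_path = out / "correlations.csv"
        if corr_path.exists():
            corr = pd.read_csv(corr_path)
            sig = corr[corr["significant"]]
            lines.append("## Partial correlations with trauma measures")
            lines.append("")
            shown = sig if len(sig) else corr.reindex(
                corr["p"].sort_values().index[:5])
            lines.append("| band | node | measure | r_partial | p |")
            lines.append("|---|---|---|---|---|")
            for _, r in shown.iterrows():
                lines.append(
                    f"| {r['band']} | {int(r['node'])} | {r['measure']} | "
                    f"{r['r_partial']:.3f} | {r['p']:.3g} |")
            lines.append("")

        text = "\n".join(lines)
        (out / "report.md").write_text(text)
        return text


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 scratch_dir: str | Path | None = None) -> PipelineRun:
    """Validate, run every stage, and return the run handle."""
    run = PipelineRun(config, outdir, scratch_dir=scratch_dir)
    run.run_all()
    return run
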