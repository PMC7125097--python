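"""Orchestration: simulate or load recordings, run every stage, aggregate
cohort statistics, and write all output artifacts.

A cohort run produces, per animal: the 10-s-mean series, six index series
(PRx, COx, HVx, wPRx, wCOx, wHVx), an LLA estimate, above/below-LLA paired
means, above-LLA index SDs, and a multi-window ABPopt per index.  Cohort
level: paired ROC per index (per-animal above/below means), DeLong
wavelet-vs-correlation comparisons, paired t tests on index SDs, and
Pearson/Bland-Altman agreement between wavelet- and correlation-derived
ABPopt.  Every artifact embeds the config hash and master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import limits
from .correlation import (
    CORRELATION_INDICES,
    WAVELET_INDICES,
    IndexSeries,
    correlation_indices,
)
from .errors import AutoregError, InputError, InsufficientDataError
from .evaluation import (
    bland_altman,
    delong_test,
    index_sd_above,
    paired_above_below,
    paired_t,
    roc_with_cutoff,
)
from .preprocess import SlowWaveSeries, block_average
from .simulate import (
    CSV_COLUMNS,
    RawRecording,
    SimulationConfig,
    generate_recording,
)
from .wavelet import WaveletConfig, wavelet_indices

log = logging.getLogger(__name__)

ALL_INDICES = CORRELATION_INDICES + WAVELET_INDICES
INDEX_PAIRS = tuple(zip(CORRELATION_INDICES, WAVELET_INDICES))  # (corr, wavelet)

_CSV_TO_CH = {
    "abp_mmhg": "abp",
    "icp_mmhg": "icp",
    "rso2_pct": "rso2",
    "rthb_au": "rthb",
    "ldf_au": "ldf",
}


@dataclass
class RunConfig:
    """Configuration of a full cohort experiment."""

    n_animals: int = 30
    seed: int = 0
    outdir: str = "autoreg_out"
    # Simulated cohort design: 5-h recordings whose ABP ramps across a
    # per-animal LLA drawn uniformly from lla_range; the optimal ABP sits
    # abpopt_offset above the LLA.
    duration_s: float = 18000.0
    abp_start: float = 85.0
    abp_end: float = 30.0
    lla_range: tuple[float, float] = (35.0, 55.0)
    abpopt_offset: float = 15.0
    sim_overrides: dict = field(default_factory=dict)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    window_samples: int = 30
    make_figures: bool = True
    write_per_animal: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        wl = obj.pop("wavelet", None)
        cfg = cls(**obj)
        if wl:
            if "band" in wl:
                wl["band"] = tuple(wl["band"])
            cfg.wavelet = WaveletConfig(**wl)
        if "lla_range" in obj:
            cfg.lla_range = tuple(obj["lla_range"])
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lla_range"] = list(self.lla_range)
        d["wavelet"]["band"] = list(self.wavelet.band)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_recording_csv(
    path: str | Path, sample_rate_hz: float | None = None, **meta
) -> RawRecording:
    """Read the canonical recording CSV, validating its schema.

    Raises :class:`InputError` naming the first offending column.
    """
    df = pd.read_csv(path, comment="#")
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    for col in CSV_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float)))].index
            row = int(bad[0]) if len(bad) else -1
            raise InputError(f"{path}: non-numeric value in column {col!r} (row {row})")
    t = df["time_s"].to_numpy(float)
    if sample_rate_hz is None:
        if len(t) < 2:
            raise InputError(f"{path}: cannot infer sample rate from one row")
        sample_rate_hz = 1.0 / float(np.median(np.diff(t)))
    channels = {ch: df[col].to_numpy(float) for col, ch in _CSV_TO_CH.items()}
    return RawRecording(channels=channels, sample_rate_hz=sample_rate_hz, **meta)


def animal_sim_config(run: RunConfig, i: int, child_seed: int) -> SimulationConfig:
    """Per-animal simulation config with its LLA drawn from the cohort range."""
    rng = np.random.default_rng(child_seed)
    lla = float(rng.uniform(*run.lla_range))
    kw = dict(
        duration_s=run.duration_s,
        abp_start=run.abp_start,
        abp_end=run.abp_end,
        lla_true=lla,
        abpopt_true=lla + run.abpopt_offset,
        seed=int(child_seed),
    )
    kw.update(run.sim_overrides)
    return SimulationConfig(**kw)


def child_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-animal seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n, dtype=np.uint32) % np.uint32(2**31)


def process_recording(
    recording: RawRecording,
    wavelet_cfg: WaveletConfig | None = None,
    window_samples: int = 30,
) -> dict:
    """Run every per-animal stage; returns a results dict.

    LLA or ABPopt failures are recorded as missing, not raised: a cohort run
    tolerates unanalyzable animals the way the original yields (66-67/68)
    did.
    """
    wavelet_cfg = wavelet_cfg or WaveletConfig()
    series = block_average(recording)
    idx: dict[str, IndexSeries] = {}
    idx.update(correlation_indices(series, window_samples=window_samples))
    idx.update(wavelet_indices(series, config=wavelet_cfg))

    out: dict = {"series": series, "indices": idx, "animal_id": recording.animal_id}
    try:
        lla_est = limits.find_lla(series)
        out["lla"] = lla_est
    except AutoregError as exc:
        log.warning("%s: LLA failed: %s", recording.animal_id, exc)
        out["lla"] = None
        return out

    out["paired"] = {
        nm: paired_above_below(idx[nm], series, lla_est.lla) for nm in ALL_INDICES
    }
    out["sd_above"] = {
        nm: index_sd_above(idx[nm], series, lla_est.lla) for nm in ALL_INDICES
    }
    out["abpopt"] = {}
    for nm in ALL_INDICES:
        try:
            out["abpopt"][nm] = limits.multiwindow_abpopt(idx[nm], series, lla_est.lla)
        except InsufficientDataError as exc:
            log.info("%s/%s: ABPopt missing: %s", recording.animal_id, nm, exc)
            out["abpopt"][nm] = limits.ABPoptEstimate(abpopt=None)
    return out


def cohort_statistics(animals: list[dict]) -> dict:
    """Aggregate cohort statistics over processed animals."""
    stats: dict = {"n_animals": len(animals)}

    # Paired per-animal above/below means -> ROC observations.
    roc: dict = {}
    for nm in ALL_INDICES:
        scores, labels = [], []
        for a in animals:
            if a.get("lla") is None:
                continue
            p = a["paired"][nm]
            if np.isfinite(p.mean_above) and np.isfinite(p.mean_below):
                scores += [p.mean_above, p.mean_below]
                labels += [False, True]
        if len(set(labels)) == 2:
            r = roc_with_cutoff(np.asarray(scores), np.asarray(labels))
            roc[nm] = {
                "n": len(scores) // 2,
                "auc": r.auc,
                "auc_p": r.auc_p_vs_chance,
                "cutoff": r.cutoff,
                "sensitivity": r.sensitivity,
                "sensitivity_ci": list(r.sensitivity_ci),
                "specificity": r.specificity,
                "specificity_ci": list(r.specificity_ci),
            }
    stats["roc"] = roc

    # DeLong wavelet vs correlation on the shared paired observations.
    stats["delong"] = {}
    for cn, wn in INDEX_PAIRS:
        sa, sb, labels = [], [], []
        for a in animals:
            if a.get("lla") is None:
                continue
            pc, pw = a["paired"][cn], a["paired"][wn]
            if all(
                np.isfinite(v)
                for v in (pc.mean_above, pc.mean_below, pw.mean_above, pw.mean_below)
            ):
                sa += [pc.mean_above, pc.mean_below]
                sb += [pw.mean_above, pw.mean_below]
                labels += [False, True]
        if len(set(labels)) == 2:
            diff, z, p = delong_test(np.asarray(sa), np.asarray(sb), np.asarray(labels))
            stats["delong"][f"{cn}_vs_{wn}"] = {"auc_diff": diff, "z": z, "p": p}

    # Index variability: per-animal SDs above the LLA, paired t per pair.
    stats["sd"] = {}
    stats["sd_ttest"] = {}
    for cn, wn in INDEX_PAIRS:
        sc = np.array(
            [a["sd_above"][cn] for a in animals if a.get("lla") is not None]
        )
        sw = np.array(
            [a["sd_above"][wn] for a in animals if a.get("lla") is not None]
        )
        ok = np.isfinite(sc) & np.isfinite(sw)
        if ok.sum() >= 2:
            t, p = paired_t(sw[ok], sc[ok])
            stats["sd"][cn] = {"mean": float(sc[ok].mean()), "sd": float(sc[ok].std(ddof=1))}
            stats["sd"][wn] = {"mean": float(sw[ok].mean()), "sd": float(sw[ok].std(ddof=1))}
            stats["sd_ttest"][f"{wn}_minus_{cn}"] = {"t": t, "p": p, "n": int(ok.sum())}

    # ABPopt agreement between methods, and identification yield per index.
    stats["abpopt_yield"] = {}
    stats["abpopt_agreement"] = {}
    for nm in ALL_INDICES:
        vals = [
            a["abpopt"][nm].abpopt
            for a in animals
            if a.get("lla") is not None and "abpopt" in a
        ]
        stats["abpopt_yield"][nm] = {
            "identified": sum(v is not None for v in vals),
            "of": len(vals),
        }
    for cn, wn in INDEX_PAIRS:
        xa, xb = [], []
        for a in animals:
            if a.get("lla") is None or "abpopt" not in a:
                continue
            va, vb = a["abpopt"][cn].abpopt, a["abpopt"][wn].abpopt
            if va is not None and vb is not None:
                xa.append(va)
                xb.append(vb)
        if len(xa) >= 3:
            ag = bland_altman(np.asarray(xa), np.asarray(xb))
            stats["abpopt_agreement"][f"{cn}_vs_{wn}"] = {
                "n": len(xa),
                "r": ag.r,
                "p": ag.r_p,
                "bias": ag.bias,
                "loa": [ag.loa_low, ag.loa_high],
            }

    llas = [a["lla"].lla for a in animals if a.get("lla") is not None]
    stats["lla"] = {
        "n": len(llas),
        "mean": float(np.mean(llas)) if llas else None,
        "sd": float(np.std(llas, ddof=1)) if len(llas) > 1 else None,
    }
    return stats


def table1_frame(stats: dict) -> pd.DataFrame:
    """Summary table of per-index discrimination (one row per index)."""
    rows = []
    for nm in ALL_INDICES:
        r = stats["roc"].get(nm)
        if r is None:
            continue
        rows.append(
            {
                "index": nm,
                "n": r["n"],
                "AUC": round(r["auc"], 3),
                "p_value": r["auc_p"],
                "cutoff": round(r["cutoff"], 3),
                "sensitivity": round(r["sensitivity"], 3),
                "sens_ci_low": round(r["sensitivity_ci"][0], 3),
                "sens_ci_high": round(r["sensitivity_ci"][1], 3),
                "specificity": round(r["specificity"], 3),
                "spec_ci_low": round(r["specificity_ci"][0], 3),
                "spec_ci_high": round(r["specificity_ci"][1], 3),
            }
        )
    return pd.DataFrame(rows)


def _provenance_line(run: RunConfig) -> str:
    return f"# autoreg config_hash={run.hash()} seed={run.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, run: RunConfig) -> None:
    with open(path, "w") as f:
        f.write(_provenance_line(run))
        df.to_csv(f, index=False)


def run_cohort(run: RunConfig, recordings: list[RawRecording] | None = None) -> dict:
    """Execute the full experiment and write all artifacts under ``outdir``.

    ``recordings`` may be supplied (loaded from CSVs); otherwise
    ``run.n_animals`` recordings are simulated from the master seed.  The
    returned dict contains the per-animal results, cohort statistics and the
    ground truths of simulated animals.  Deterministic: the same config and
    seed rewrite byte-identical JSON.
    """
    logging.basicConfig(level=run.log_level)
    outdir = Path(run.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truths = []
    if recordings is None:
        recordings = []
        for i, cs in enumerate(child_seeds(run.seed, run.n_animals)):
            cfg = animal_sim_config(run, i, int(cs))
            rec, truth = generate_recording(cfg)
            rec.animal_id = f"sim-{i:03d}"
            rec.group = "arrest" if i % 2 == 0 else "sham"
            recordings.append(rec)
            truths.append(truth)

    animals = []
    for rec in recordings:
        res = process_recording(
            rec, wavelet_cfg=run.wavelet, window_samples=run.window_samples
        )
        animals.append(res)
        if run.write_per_animal:
            adir = outdir / rec.animal_id
            adir.mkdir(exist_ok=True)
            _write_csv(res["series"].to_frame(), adir / "slow_waves.csv", run)
            idx_df = pd.DataFrame({"time_s": res["series"].time_s})
            for nm in ALL_INDICES:
                idx_df[nm] = res["indices"][nm].values
            _write_csv(idx_df, adir / "indices.csv", run)

    stats = cohort_statistics(animals)

    results = {
        "config_hash": run.hash(),
        "seed": run.seed,
        "config": run.to_dict(),
        "cohort": stats,
        "animals": [_animal_json(a) for a in animals],
    }
    (outdir / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    _write_csv(table1_frame(stats), outdir / "table1.csv", run)

    if run.make_figures:
        try:
            _figures(animals, outdir, run)
        except Exception as exc:  # figures are best-effort side outputs
            log.warning("figure generation failed: %s", exc)

    return {"animals": animals, "stats": stats, "truths": truths, "outdir": outdir}


def _animal_json(a: dict) -> dict:
    out = {"animal_id": a["animal_id"]}
    if a.get("lla") is not None:
        est = a["lla"]
        out["lla"] = {
            "lla": est.lla,
            "breakpoint": est.breakpoint,
            "sse": est.sse,
            "n_left": est.n_left,
            "n_right": est.n_right,
        }
        out["paired"] = {
            nm: {
                "above": _jf(p.mean_above),
                "below": _jf(p.mean_below),
                "one_sided": p.one_sided,
            }
            for nm, p in a["paired"].items()
        }
        out["sd_above"] = {nm: _jf(v) for nm, v in a["sd_above"].items()}
        out["abpopt"] = {
            nm: {
                "abpopt": est.abpopt,
                "windows": [
                    {
                        "window_s": w.window_s,
                        "vertex": w.vertex,
                        "fit_error": w.fit_error,
                        "shape": w.shape,
                        "weight": w.weight,
                    }
                    for w in est.windows
                ],
            }
            for nm, est in a.get("abpopt", {}).items()
        }
    else:
        out["lla"] = None
    return out


def _jf(v: float) -> float | None:
    return None if v is None or not np.isfinite(v) else float(v)


def _figures(animals: list[dict], outdir: Path, run: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    meta = {"Description": f"autoreg config_hash={run.hash()} seed={run.seed}"}

    # Pooled U-curves: per index, bin every animal's above-LLA 5-min samples.
    fig, axes = plt.subplots(2, 3, figsize=(12, 7), sharex=True)
    for ax, nm in zip(axes.ravel(), ALL_INDICES):
        med_all, idx_all = [], []
        for a in animals:
            if a.get("lla") is None:
                continue
            series, index = a["series"], a["indices"][nm]
            abp = series["abp"]
            above = np.isfinite(abp) & (abp > a["lla"].lla)
            masked = IndexSeries(
                name=nm, time_s=index.time_s, values=np.where(above, index.values, np.nan)
            )
            masked_series = SlowWaveSeries(
                time_s=series.time_s,
                channels={"abp": np.where(above, abp, np.nan)},
                block_s=series.block_s,
            )
            med, mi, _ = limits.median_abp_epochs(masked_series, masked)
            med_all += list(med)
            idx_all += list(mi)
        if med_all:
            curve = limits.bin_index_curve(np.asarray(med_all), np.asarray(idx_all))
            occ = curve.occupied
            ax.errorbar(
                curve.centers[occ], curve.mean_z[occ], yerr=curve.sem_z[occ], fmt="o-"
            )
        ax.set_title(nm)
        ax.set_xlabel("ABP (mmHg)")
        ax.set_ylabel("Fisher z")
    fig.suptitle("Pooled index vs ABP curves (above-LLA samples)")
    fig.tight_layout()
    fig.savefig(outdir / "u_curves.png", dpi=110, metadata=meta)
    plt.close(fig)

    # Bland-Altman per index pair on ABPopt.
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, (cn, wn) in zip(axes, INDEX_PAIRS):
        xa, xb = [], []
        for a in animals:
            if a.get("lla") is None or "abpopt" not in a:
                continue
            va, vb = a["abpopt"][cn].abpopt, a["abpopt"][wn].abpopt
            if va is not None and vb is not None:
                xa.append(va)
                xb.append(vb)
        if len(xa) >= 3:
            ag = bland_altman(np.asarray(xa), np.asarray(xb))
            mean_ab = (np.asarray(xa) + np.asarray(xb)) / 2
            ax.scatter(mean_ab, np.asarray(xa) - np.asarray(xb), s=14)
            for yv, ls in ((ag.bias, "-"), (ag.loa_low, "--"), (ag.loa_high, "--")):
                ax.axhline(yv, color="k", linestyle=ls, linewidth=0.8)
        ax.set_title(f"{cn} vs {wn}")
        ax.set_xlabel("mean ABPopt (mmHg)")
        ax.set_ylabel("difference (mmHg)")
    fig.suptitle("ABPopt agreement (correlation minus wavelet)")
    fig.tight_layout()
    fig.savefig(outdir / "abpopt_bland_altman.png", dpi=110, metadata=meta)
    plt.close(fig)
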