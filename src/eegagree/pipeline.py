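"""End-to-end study pipeline: simulate -> preprocess -> MMN/theta ->
connectivity -> agreement.

Each synthetic subject is recorded with both systems (wet and dry caps),
runs the oddball task and a resting-state block, and is pushed through
the full analysis chain.  Per-subject results are cached as JSON keyed by
a hash of the run configuration, so re-running a partially complete
output directory only recomputes what is missing; group-level statistics
are always recomputed from the per-subject table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import agreement as agr
from .connectivity import BANDS, analyze_connectivity
from .evoked import (MMN_WINDOW, analyze_mmn, average_and_baseline,
                     select_trials)
from .layouts import DEFAULT_LAYOUTS, get_layout
from .preprocess import PreprocConfig, preprocess_rest, preprocess_task
from .sequence import generate_sequence
from .synth import (GroundTruth, synthesize_resting_recording,
                    synthesize_task_recording)
from .timefreq import db_baseline, extract_theta, morlet_tfr


@dataclass
class SequenceConfig:
    n_standards: int = 612
    n_deviants_per_type: int = 102
    min_gap: int = 2
    max_gap: int = 4
    soa: float = 1.555
    n_habituation: int = 10


@dataclass
class RunConfig:
    """Full study configuration; serialized verbatim into the output dir."""

    seed: int = 0
    n_subjects: int = 23
    systems: Tuple[str, ...] = ("wet", "dry")
    out_dir: str = "run_out"
    sequence: SequenceConfig = field(default_factory=SequenceConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    rest_duration: float = 300.0
    mmn_window: Tuple[float, float] = MMN_WINDOW
    # across-subject variability of the injected deviant negativity
    mmn_amplitude_mean: float = -3.5e-6
    mmn_amplitude_sd: float = 1.0e-6
    theta_burst_gain: float = 3.0
    n_coupled_pairs: int = 8
    resting_lag: float = np.pi / 4
    resting_coupling: float = 0.6
    do_task: bool = True
    do_rest: bool = True
    do_stats: bool = True
    make_plots: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["systems"] = list(self.systems)
        d["mmn_window"] = list(self.mmn_window)
        d["preproc"]["band"] = list(self.preproc.band)
        return d

    def hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sequence" in d:
            d["sequence"] = SequenceConfig(**d["sequence"])
        if "preproc" in d:
            p = dict(d["preproc"])
            if "band" in p:
                p["band"] = tuple(p["band"])
            d["preproc"] = PreprocConfig(**p)
        if "systems" in d:
            d["systems"] = tuple(d["systems"])
        if "mmn_window" in d:
            d["mmn_window"] = tuple(d["mmn_window"])
        return cls(**d)


def make_subject_truth(cfg: RunConfig, subject: int) -> GroundTruth:
    """Draw one subject's ground truth (seeded by run seed and subject)."""
    rng = np.random.default_rng([cfg.seed, subject, 7])
    lags: Dict[str, dict] = {}
    coup: Dict[str, dict] = {}
    for band in BANDS:
        lags[band] = {}
        coup[band] = {}
        for system in cfg.systems:
            lay = get_layout(DEFAULT_LAYOUTS[system])
            scalp = list(lay.scalp)
            pairs = set()
            while len(pairs) < cfg.n_coupled_pairs:
                i, j = rng.choice(len(scalp), size=2, replace=False)
                pairs.add((scalp[int(i)], scalp[int(j)]))
            for p in pairs:
                lags[band][p] = cfg.resting_lag
                coup[band][p] = cfg.resting_coupling
    return GroundTruth(
        mmn_amplitude=float(rng.normal(cfg.mmn_amplitude_mean, cfg.mmn_amplitude_sd)),
        theta_burst_gain=cfg.theta_burst_gain,
        resting_phase_lags=lags,
        resting_coupling=coup,
        seed=int(rng.integers(2**31 - 1)),
    )


def _available_count(erp) -> int:
    """Equalized per-condition trial count available after exclusions."""
    kept = erp.info[erp.kept_mask]
    dev = kept["condition"].isin(["deviant_low", "deviant_high", "deviant"])
    std_ok = ((kept["condition"] == "standard")
              & ~kept["is_habituation"] & ~kept["follows_deviant"])
    return int(min(dev.sum(), std_ok.sum()))


def process_subject(cfg: RunConfig, subject: int) -> dict:
    """Run both systems of one synthetic subject through the full chain."""
    truth = make_subject_truth(cfg, subject)
    row: dict = {"subject": subject,
                 "truth_mmn_amplitude": truth.mmn_amplitude}
    per_system: Dict[str, dict] = {}

    if cfg.do_task:
        erps, tfrs, reports = {}, {}, {}
        for k, system in enumerate(cfg.systems):
            seq = generate_sequence(
                cfg.sequence.n_standards, cfg.sequence.n_deviants_per_type,
                cfg.sequence.min_gap, cfg.sequence.max_gap, cfg.sequence.soa,
                cfg.sequence.n_habituation, seed=int(1000 * subject + k + cfg.seed),
            )
            rec = synthesize_task_recording(
                seq, truth, layout=DEFAULT_LAYOUTS[system], system=system,
                seed=truth.seed,
            )
            pc = dataclasses.replace(cfg.preproc, seed=cfg.seed + subject)
            erps[system], tfrs[system], reports[system] = preprocess_task(rec, pc)
        n_common = min(_available_count(erps[s]) for s in cfg.systems)
        for system in cfg.systems:
            lay = get_layout(DEFAULT_LAYOUTS[system])
            erp = erps[system]
            res = analyze_mmn(erp, seed=cfg.seed + subject, n_max=n_common,
                              window=cfg.mmn_window)
            rep = reports[system]
            rep.decide_inclusion(res.snr, cfg.preproc.min_fraction_retained,
                                 cfg.preproc.min_snr)
            sel = select_trials(erp, seed=cfg.seed + subject, n_max=n_common)
            ev_dev = average_and_baseline(sel, "deviant")
            ev_std = average_and_baseline(sel, "standard")
            ci = ev_dev.channel_labels.index(lay.mmn_channel)
            times = ev_dev.times
            wmask = (times >= cfg.mmn_window[0]) & (times <= cfg.mmn_window[1])
            sel_tfr = select_trials(tfrs[system], seed=cfg.seed + subject,
                                    n_max=n_common)
            t_dev = db_baseline(morlet_tfr(sel_tfr, "deviant"))
            t_std = db_baseline(morlet_tfr(sel_tfr, "standard"))
            th_dev, th_std, th_diff = extract_theta(t_dev, t_std, lay.mmn_channel)
            per_system[system] = dict(
                included=bool(rep.included),
                fraction_retained=rep.fraction_trials_retained,
                n_channels_rejected=rep.n_channels_rejected,
                n_components_rejected=rep.n_components_rejected,
                n_trials_used=res.n_trials_used,
                snr=res.snr,
                mmn_mean_amplitude=res.mean_amplitude,
                mmn_peak_amplitude=res.peak_amplitude,
                mmn_peak_latency=res.peak_latency,
                amp_standard=float(ev_std.data[ci, wmask].mean()),
                amp_deviant=float(ev_dev.data[ci, wmask].mean()),
                theta_standard=th_std,
                theta_deviant=th_dev,
                theta_diff=th_diff,
                reasons=rep.reasons,
                diff_wave=(ev_dev.data[ci] - ev_std.data[ci]).tolist(),
                diff_wave_tmin=float(times[0]),
                diff_wave_fs=float(ev_dev.fs),
            )

    if cfg.do_rest:
        for system in cfg.systems:
            rec = synthesize_resting_recording(
                truth, layout=DEFAULT_LAYOUTS[system], system=system,
                duration=cfg.rest_duration, seed=truth.seed,
            )
            pc = dataclasses.replace(cfg.preproc, seed=cfg.seed + subject)
            eps, _ = preprocess_rest(rec, pc)
            conn = analyze_connectivity(eps)
            d = per_system.setdefault(system, {})
            for band, r in conn.items():
                d[f"pli_{band}"] = r["mean_pli"]
                d[f"mst_diameter_{band}"] = r["diameter"]
                d[f"mst_d_{band}"] = r["d"]
                d[f"mst_M_{band}"] = r["M"]

    row["systems"] = per_system
    return row


TASK_MEASURES = ["mmn_mean_amplitude", "mmn_peak_amplitude",
                 "mmn_peak_latency", "theta_diff"]
REST_MEASURES = ([f"pli_{b}" for b in BANDS]
                 + [f"mst_diameter_{b}" for b in BANDS])


def _subject_table(rows: List[dict], systems) -> pd.DataFrame:
    recs = []
    for row in rows:
        for system, d in row["systems"].items():
            rec = {k: v for k, v in d.items()
                   if not isinstance(v, (list, dict))}
            rec.update(subject=row["subject"], system=system,
                       truth_mmn_amplitude=row["truth_mmn_amplitude"])
            recs.append(rec)
    return pd.DataFrame(recs)


def group_statistics(table: pd.DataFrame, systems=("wet", "dry")) -> dict:
    """Agreement and hypothesis tests over the per-subject table."""
    wet, dry = systems
    piv = {s: table[table.system == s].set_index("subject") for s in systems}
    common = piv[wet].index.intersection(piv[dry].index)

    task_ok = common
    if "included" in table.columns:
        inc = [s for s in common
               if bool(piv[wet].loc[s].get("included", False))
               and bool(piv[dry].loc[s].get("included", False))]
        task_ok = pd.Index(inc)

    out: dict = {"n_subjects": int(len(common)),
                 "n_included_task": int(len(task_ok)),
                 "agreement": {}, "tests": {}}
    measures = []
    for m in TASK_MEASURES:
        if m in table.columns:
            measures.append((m, task_ok))
    for m in REST_MEASURES:
        if m in table.columns:
            measures.append((m, common))
    for m, idx in measures:
        if len(idx) < 3:
            continue
        pm = agr.PairedMeasures(
            subject_id=list(idx),
            value_wet=piv[wet].loc[idx, m].to_numpy(),
            value_dry=piv[dry].loc[idx, m].to_numpy(),
            measure_name=m,
        )
        try:
            r = agr.bland_altman(pm)
        except ValueError:
            continue
        diffs = pm.diffs()
        d_val = (agr.cohens_d_paired(diffs) if diffs.std(ddof=1) > 0 else 0.0)
        out["agreement"][m] = dict(
            bias=r.bias, ci=list(r.bias_ci), loa=[r.loa_low, r.loa_high],
            n=r.n, sd_diff=r.sd_diff, cohen_d=d_val,
            label=agr.effect_size_label(d_val),
            significant=r.bias_significant,
        )

    # 2x2 system-by-tone ANOVA on window amplitude and theta power
    for name, cols in [("mean_amplitude", ("amp_standard", "amp_deviant")),
                       ("theta_power", ("theta_standard", "theta_deviant"))]:
        if cols[0] not in table.columns or len(task_ok) < 3:
            continue
        y = np.array([
            [[piv[s].loc[sub, cols[0]], piv[s].loc[sub, cols[1]]]
             for s in systems]
            for sub in task_ok
        ])
        res = agr.rm_anova_2x2(y, factor_names=("system", "tone"))
        out["tests"][name] = [dataclasses.asdict(t) for t in res]
        # post-hoc one-sided paired tests per system (deviant < / > standard)
        direction = "less" if name == "mean_amplitude" else "greater"
        for si, s in enumerate(systems):
            pm = agr.PairedMeasures(
                subject_id=list(task_ok),
                value_wet=y[:, si, 1], value_dry=y[:, si, 0],
                measure_name=f"{name} deviant vs standard ({s})",
            )
            try:
                t = agr.paired_tests(pm, sided="one", direction=direction,
                                     bonferroni_m=len(systems))
                out["tests"][f"{name}_posthoc_{s}"] = dataclasses.asdict(t)
            except ZeroDivisionError:
                pass
    if len(task_ok) >= 3 and "snr" in table.columns:
        out["group_snr"] = {s: float(piv[s].loc[task_ok, "snr"].mean())
                            for s in systems}
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all enabled stages; returns the study-level results bundle.

    Output directory layout::

        config.yaml              run configuration as given
        subjects/sub-NNN.json    per-subject results (cache key = config hash)
        subjects.csv             tidy per-subject x system table
        group_stats.json         agreement + tests
        run.json                 run report (inclusion bookkeeping)
    """
    import yaml

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "subjects").mkdir(exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    chash = cfg.hash()

    rows = []
    for subject in range(cfg.n_subjects):
        cache = out / "subjects" / f"sub-{subject:03d}.json"
        row = None
        if cache.exists():
            try:
                with open(cache) as fh:
                    cached = json.load(fh)
                if cached.get("config_hash") == chash:
                    row = cached["row"]
            except (json.JSONDecodeError, KeyError):
                warnings.warn(f"corrupted cache {cache}; recomputing")
        if row is None:
            try:
                row = process_subject(cfg, subject)
            except Exception as err:
                raise RuntimeError(
                    f"subject {subject} failed in pipeline: {err}") from err
            with open(cache, "w") as fh:
                json.dump({"config_hash": chash, "row": row}, fh)
        rows.append(row)

    table = _subject_table(rows, cfg.systems)
    table.to_csv(out / "subjects.csv", index=False)

    stats = {}
    if cfg.do_stats and not table.empty:
        stats = group_statistics(table, cfg.systems)
        with open(out / "group_stats.json", "w") as fh:
            json.dump(stats, fh, indent=2)
        if cfg.make_plots:
            _make_plots(rows, stats, table, cfg, out)

    report = {
        "config_hash": chash,
        "n_subjects": cfg.n_subjects,
        "systems": list(cfg.systems),
        "excluded": [
            {"subject": r["subject"], "system": s,
             "reasons": d.get("reasons", [])}
            for r in rows for s, d in r["systems"].items()
            if d.get("included") is False
        ],
    }
    if "group_snr" in stats:
        report["group_snr"] = stats["group_snr"]
    with open(out / "run.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return {"table": table, "stats": stats, "report": report, "rows": rows}


def _make_plots(rows, stats, table, cfg, out: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    # group-average difference waves
    fig, ax = plt.subplots(figsize=(6, 4))
    for system in cfg.systems:
        waves, tmin, fs = [], None, None
        for r in rows:
            d = r["systems"].get(system, {})
            if "diff_wave" in d:
                waves.append(d["diff_wave"])
                tmin, fs = d["diff_wave_tmin"], d["diff_wave_fs"]
        if waves:
            w = np.mean(np.array(waves), axis=0) * 1e6
            t = tmin + np.arange(w.size) / fs
            ax.plot(t, w, label=system)
    ax.axvspan(*cfg.mmn_window, alpha=0.15, color="gray")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("deviant - standard (uV)")
    ax.legend()
    fig.savefig(figdir / "difference_waves.png", dpi=150)
    plt.close(fig)

    piv = {s: table[table.system == s].set_index("subject") for s in cfg.systems}
    for m in stats.get("agreement", {}):
        idx = piv[cfg.systems[0]].index.intersection(piv[cfg.systems[1]].index)
        pm = agr.PairedMeasures(
            subject_id=list(idx),
            value_wet=piv[cfg.systems[0]].loc[idx, m].to_numpy(),
            value_dry=piv[cfg.systems[1]].loc[idx, m].to_numpy(),
            measure_name=m,
        )
        try:
            ax = agr.bland_altman_plot(pm)
        except ValueError:
            continue
        ax.figure.savefig(figdir / f"bland_altman_{m}.png", dpi=150)
        plt.close(ax.figure)
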