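"""Config-driven end-to-end analysis on a cohort.

Graph (mirroring the analysis chain): stage -> NREM/REM epoch pairs ->
{PSD, coherence, PAC} -> ripple detection -> ripple-triggered coupling ->
group statistics. Runs either on a synthetic two-genotype cohort (the demo)
or on recordings loaded from files; every stage writes a plain CSV, so any
stage can be recomputed from the saved intermediates, and the whole run is
byte-deterministic under a fixed master seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling as cpl
from . import synth
from .connectivity import connectivity_table
from .errors import ConfigurationError
from .io import (
    Recording,
    read_recording,
    write_events,
    write_hypnogram,
)
from .pac import comodulogram, pac_summary
from .ripples import RippleConfig, detect_ripples, ripple_stats
from .spectral import average_spectra, notch_mask, welch_psd
from .staging import StagingThresholds, select_epoch_pairs, stage
from .stats import bh_fdr, compare_spectra, permutation_test, two_sample_ttest

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    seed: int = 7
    out_dir: str = "results"
    # synthetic cohort (ignored when animal_files is given)
    n_wt: int = 3
    n_tg: int = 3
    session_s: float = 600.0
    fs: float = 2000.0
    wt_overrides: dict = field(default_factory=dict)  # nested SynthParams overrides
    tg_overrides: dict = field(default_factory=lambda: {"coupling": {"gain": 0.0}})
    animal_files: list = field(default_factory=list)  # [{path, format, animal, genotype}]
    # channels / analyses
    screw_channel: str = "sFC"
    emg_channel: str = "EMG"
    ca1_channel: str = "CA1"
    mfc_channel: str = "mFC"
    pac_channel: str = "DG"
    psd_channels: tuple = ("sFC", "mFC", "Th-RT", "RS")
    pairs: tuple = (("mFC", "CA1"), ("mFC", "RS"), ("CA1", "DG"))
    analyses: tuple = ("psd", "connectivity", "pac", "ripples", "coupling")
    # parameters
    cap: int = 585
    alpha: float = 0.05
    n_perm: int = 10_000
    line_hz: float = 50.0
    line_half_width_hz: float = 1.0
    ripple_mode: str = "band"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.pairs:
            cfg.pairs = tuple(tuple(p) for p in cfg.pairs)
        cfg.psd_channels = tuple(cfg.psd_channels)
        cfg.analyses = tuple(cfg.analyses)
        return cfg


def _apply_overrides(params: synth.SynthParams, overrides: dict) -> synth.SynthParams:
    """Apply nested {section: {field: value}} overrides to SynthParams."""
    for section, values in overrides.items():
        if not hasattr(params, section):
            raise ConfigurationError(f"unknown SynthParams section {section!r}")
        target = getattr(params, section)
        if dataclasses.is_dataclass(target) and isinstance(values, dict):
            setattr(params, section, dataclasses.replace(target, **values))
        else:
            setattr(params, section, values)
    return params


def _build_cohort(cfg: PipelineConfig) -> list[Recording]:
    if cfg.animal_files:
        recs = []
        for entry in cfg.animal_files:
            rec = read_recording(entry["path"], format=entry.get("format", "container"))
            rec.meta["animal"] = entry.get("animal", Path(entry["path"]).stem)
            rec.meta["genotype"] = entry.get("genotype", "NA")
            recs.append(rec)
        return recs
    schedule = synth.default_schedule(cfg.session_s)
    base = synth.SynthParams(fs=cfg.fs, bout_schedule=schedule)
    p_wt = _apply_overrides(dataclasses.replace(base), dict(cfg.wt_overrides))
    p_tg = _apply_overrides(
        synth.SynthParams(fs=cfg.fs, bout_schedule=list(schedule)), dict(cfg.tg_overrides)
    )
    return synth.two_group_experiment(p_wt, p_tg, (cfg.n_wt, cfg.n_tg), seed=cfg.seed)


def _validate_channels(cfg: PipelineConfig, recordings: list[Recording]) -> None:
    needed = {cfg.screw_channel, cfg.emg_channel, cfg.ca1_channel, cfg.mfc_channel, cfg.pac_channel}
    needed |= set(cfg.psd_channels)
    for a, b in cfg.pairs:
        needed |= {a, b}
    for rec in recordings:
        missing = needed - set(rec.channel_names)
        if missing:
            raise ConfigurationError(
                f"animal {rec.meta.get('animal')}: missing channels {sorted(missing)}"
            )


def validate_config(cfg: PipelineConfig) -> None:
    """Check channel references against the synthetic layout before compute."""
    if not cfg.animal_files:
        names = {c.name for c in synth.CHANNEL_LAYOUT}
        needed = {cfg.screw_channel, cfg.emg_channel, cfg.ca1_channel, cfg.mfc_channel, cfg.pac_channel}
        needed |= set(cfg.psd_channels)
        for a, b in cfg.pairs:
            needed |= {a, b}
        missing = needed - names
        if missing:
            raise ConfigurationError(f"config references unknown channels {sorted(missing)}")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every enabled stage; returns a bundle of DataFrames and writes CSVs."""
    t_start = time.time()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_entries: list[dict] = []

    def log(stage_name: str, **info) -> None:
        log_entries.append({"stage": stage_name, **info})

    validate_config(cfg)
    recordings = _build_cohort(cfg)
    _validate_channels(cfg, recordings)
    log("cohort", n_animals=len(recordings), seed=cfg.seed,
        animals=[r.meta.get("animal") for r in recordings])

    bundle: dict = {"out_dir": str(out)}

    # --- staging -----------------------------------------------------------
    hypnograms = []
    epoch_pairs_by_animal = []
    for rec in recordings:
        hyp = stage(rec, StagingThresholds(),
                    screw_channel=cfg.screw_channel, emg_channel=cfg.emg_channel)
        hypnograms.append(hyp)
        pairs = select_epoch_pairs(hyp)
        epoch_pairs_by_animal.append(pairs)
        write_hypnogram(hyp, out / f"hypnogram_{rec.meta['animal']}.csv")
        log("staging", animal=rec.meta["animal"], n_bins=hyp.n_bins,
            n_epoch_pairs=len(pairs),
            seconds={s: hyp.state_seconds(s) for s in ("MOVE", "WI", "NREM", "REM")})

    stat_rows: list[dict] = []

    # --- power spectra -----------------------------------------------------
    if "psd" in cfg.analyses:
        psd_rows = []
        spectra_by_panel: dict[tuple, dict[str, list]] = {}
        for rec, pairs in zip(recordings, epoch_pairs_by_animal):
            for state in ("NREM", "REM"):
                for ch in cfg.psd_channels:
                    epoch_spectra = []
                    for ep in pairs:
                        seg = ep.nrem_segment(rec) if state == "NREM" else ep.rem_segment(rec)
                        epoch_spectra.append(
                            welch_psd(seg.channel(ch), rec.fs, fmin=1.0, fmax=100.0,
                                      channel=ch, state=state)
                        )
                    if not epoch_spectra:
                        continue
                    spec = notch_mask(average_spectra(epoch_spectra),
                                      cfg.line_hz, cfg.line_half_width_hz)
                    key = (ch, state)
                    spectra_by_panel.setdefault(key, {"WT": [], "TG": []})
                    spectra_by_panel[key].setdefault(rec.meta["genotype"], [])
                    spectra_by_panel[key][rec.meta["genotype"]].append(spec)
                    for fr, ps in zip(spec.freqs, spec.psd):
                        psd_rows.append(
                            {"animal": rec.meta["animal"], "genotype": rec.meta["genotype"],
                             "state": state, "channel": ch, "freq_hz": fr, "psd": ps}
                        )
        psd_table = pd.DataFrame(psd_rows)
        psd_table.to_csv(out / "psd.csv", index=False, float_format=FLOAT_FMT)
        bundle["psd"] = psd_table

        psd_stats = []
        for (ch, state), groups in sorted(spectra_by_panel.items()):
            if len(groups.get("WT", [])) >= 2 and len(groups.get("TG", [])) >= 2:
                res = compare_spectra(groups["TG"], groups["WT"], alpha=cfg.alpha)
                res.insert(0, "state", state)
                res.insert(0, "channel", ch)
                psd_stats.append(res)
        if psd_stats:
            psd_stats = pd.concat(psd_stats, ignore_index=True)
            psd_stats.to_csv(out / "psd_stats.csv", index=False, float_format=FLOAT_FMT)
            bundle["psd_stats"] = psd_stats
        log("psd", n_rows=len(psd_table))

    # --- connectivity ------------------------------------------------------
    if "connectivity" in cfg.analyses:
        conn = connectivity_table(recordings, hypnograms, pairs=cfg.pairs)
        conn.to_csv(out / "connectivity.csv", index=False, float_format=FLOAT_FMT)
        bundle["connectivity"] = conn
        conn_stats = []
        for (state, band), sub in conn.groupby(["state", "band"], sort=True):
            rows = []
            for pair_name, pair_sub in sub.groupby("pair", sort=True):
                wt = pair_sub.loc[pair_sub.genotype == "WT", "coherence"].to_numpy()
                tg = pair_sub.loc[pair_sub.genotype == "TG", "coherence"].to_numpy()
                if len(wt) >= 2 and len(tg) >= 2:
                    p = permutation_test(tg, wt, n_perm=cfg.n_perm, seed=cfg.seed)
                    rows.append({"state": state, "band": band, "pair": pair_name,
                                 "statistic": float(tg.mean() - wt.mean()), "p": p})
            if rows:  # BH family: all pairs within one state x band set
                fam = pd.DataFrame(rows)
                q, rej = bh_fdr(fam["p"].to_numpy(), alpha=cfg.alpha)
                fam["q"], fam["significant"] = q, rej
                conn_stats.append(fam)
        if conn_stats:
            conn_stats = pd.concat(conn_stats, ignore_index=True)
            conn_stats.to_csv(out / "connectivity_stats.csv", index=False, float_format=FLOAT_FMT)
            bundle["connectivity_stats"] = conn_stats
        log("connectivity", n_rows=len(conn))

    # --- phase-amplitude coupling (REM, hippocampus) -----------------------
    if "pac" in cfg.analyses:
        pac_rows = []
        for rec, pairs in zip(recordings, epoch_pairs_by_animal):
            segments = [ep.rem_segment(rec).channel(cfg.pac_channel) for ep in pairs]
            if not segments:
                continue
            como = comodulogram(
                segments, rec.fs,
                phase_freqs=np.array([7.0, 8.0]),
                amp_freqs=np.arange(60.0, 95.0, 5.0),
                channel=cfg.pac_channel, state="REM",
            )
            pac_rows.append(
                {"animal": rec.meta["animal"], "genotype": rec.meta["genotype"],
                 "mean_mi": pac_summary(como), "n_segments": len(segments)}
            )
        pac_table = pd.DataFrame(pac_rows)
        pac_table.to_csv(out / "pac.csv", index=False, float_format=FLOAT_FMT)
        bundle["pac"] = pac_table
        wt = pac_table.loc[pac_table.genotype == "WT", "mean_mi"].to_numpy()
        tg = pac_table.loc[pac_table.genotype == "TG", "mean_mi"].to_numpy()
        if len(wt) >= 2 and len(tg) >= 2:
            t, p = two_sample_ttest(tg, wt)
            stat_rows.append({"comparison": "pac_mean_mi", "statistic": t, "p": p,
                              "n_tg": len(tg), "n_wt": len(wt), "method": "ttest"})
        log("pac", n_animals=len(pac_table))

    # --- ripples -----------------------------------------------------------
    ripple_events_by_animal: dict[str, object] = {}
    if "ripples" in cfg.analyses or "coupling" in cfg.analyses:
        rip_rows = []
        rcfg = RippleConfig(mode=cfg.ripple_mode)
        for rec, hyp in zip(recordings, hypnograms):
            events = detect_ripples(rec, cfg.ca1_channel, hyp, rcfg)
            ripple_events_by_animal[rec.meta["animal"]] = events
            write_events(events, out / f"ripples_{rec.meta['animal']}.csv")
            st = ripple_stats(events, hyp)
            for _, row in st.iterrows():
                rip_rows.append({"animal": rec.meta["animal"],
                                 "genotype": rec.meta["genotype"], **row.to_dict()})
            log("ripples", animal=rec.meta["animal"], n_events=len(events))
        rip_table = pd.DataFrame(rip_rows)
        rip_table.to_csv(out / "ripple_stats.csv", index=False, float_format=FLOAT_FMT)
        bundle["ripple_stats"] = rip_table
        for state in ("NREM", "WI"):
            for metric in ("rate_per_min", "mean_intra_freq_hz", "mean_duration_ms"):
                sub = rip_table[rip_table.state == state].dropna(subset=[metric])
                wt = sub.loc[sub.genotype == "WT", metric].to_numpy()
                tg = sub.loc[sub.genotype == "TG", metric].to_numpy()
                if len(wt) >= 2 and len(tg) >= 2:
                    t, p = two_sample_ttest(tg, wt)
                    stat_rows.append({"comparison": f"ripple_{state}_{metric}",
                                      "statistic": t, "p": p,
                                      "n_tg": len(tg), "n_wt": len(wt), "method": "ttest"})

    # --- ripple-triggered coupling -----------------------------------------
    if "coupling" in cfg.analyses:
        coup_rows = []
        for rec in recordings:
            events = ripple_events_by_animal.get(rec.meta["animal"])
            try:
                tp = cpl.ripple_triggered_spindle_power(
                    rec, cfg.mfc_channel, events, cap=cfg.cap
                )
            except Exception as exc:  # animals without usable ripples are dropped
                warnings.warn(f"coupling skipped for {rec.meta['animal']}: {exc}")
                log("coupling", animal=rec.meta["animal"], skipped=str(exc))
                continue
            coup_rows.append(
                {"animal": rec.meta["animal"], "genotype": rec.meta["genotype"],
                 "peak_norm_power": tp.peak_norm_power,
                 "baseline_power": tp.baseline_power, "n_events": tp.n_events}
            )
            log("coupling", animal=rec.meta["animal"], n_events=tp.n_events)
        coup_table = pd.DataFrame(coup_rows)
        coup_table.to_csv(out / "coupling.csv", index=False, float_format=FLOAT_FMT)
        bundle["coupling"] = coup_table
        for metric in ("peak_norm_power", "baseline_power"):
            if len(coup_table):
                wt = coup_table.loc[coup_table.genotype == "WT", metric].to_numpy()
                tg = coup_table.loc[coup_table.genotype == "TG", metric].to_numpy()
                if len(wt) >= 2 and len(tg) >= 2:
                    t, p = two_sample_ttest(tg, wt)
                    stat_rows.append({"comparison": f"coupling_{metric}", "statistic": t,
                                      "p": p, "n_tg": len(tg), "n_wt": len(wt),
                                      "method": "ttest"})

    stats_table = pd.DataFrame(
        stat_rows, columns=["comparison", "statistic", "p", "n_tg", "n_wt", "method"]
    )
    stats_table.to_csv(out / "group_stats.csv", index=False, float_format=FLOAT_FMT)
    bundle["group_stats"] = stats_table

    log("done", elapsed_s=round(time.time() - t_start, 3))
    with open(log_path, "w") as f:
        for entry in log_entries:
            f.write(json.dumps(entry, sort_keys=True) + "\n")
    bundle["log"] = log_entries

    report = make_report(bundle)
    for name, frame in report.items():
        frame.to_csv(out / f"report_{name}.csv", index=False, float_format=FLOAT_FMT)
    bundle["report"] = report
    return bundle


def _mean_sem(sub: pd.DataFrame, value: str, by: list[str]) -> pd.DataFrame:
    g = sub.groupby(by, sort=True)[value]
    res = g.agg(["mean", "sem", "count"]).reset_index()
    res["sem"] = res["sem"].fillna(0.0)
    return res.rename(columns={"count": "n"})


def make_report(bundle: dict) -> dict[str, pd.DataFrame]:
    """Per-genotype mean ± SEM summary tables for each computed analysis."""
    report: dict[str, pd.DataFrame] = {}
    if "ripple_stats" in bundle and len(bundle["ripple_stats"]):
        rows = []
        rs = bundle["ripple_stats"]
        for metric, label in [("rate_per_min", "rate_per_min"),
                              ("mean_intra_freq_hz", "frequency_hz"),
                              ("mean_duration_ms", "duration_ms")]:
            sub = rs.dropna(subset=[metric])
            res = _mean_sem(sub, metric, ["state", "genotype"])
            res.insert(0, "metric", label)
            rows.append(res.rename(columns={metric: "value"}))
        report["ripples"] = pd.concat(rows, ignore_index=True)
    if "connectivity" in bundle and len(bundle["connectivity"]):
        report["connectivity"] = _mean_sem(
            bundle["connectivity"], "coherence", ["state", "pair", "band", "genotype"]
        )
    if "pac" in bundle and len(bundle["pac"]):
        report["pac"] = _mean_sem(bundle["pac"], "mean_mi", ["genotype"])
    if "coupling" in bundle and len(bundle["coupling"]):
        peak = _mean_sem(bundle["coupling"], "peak_norm_power", ["genotype"])
        peak.insert(0, "metric", "peak_norm_power")
        base = _mean_sem(bundle["coupling"], "baseline_power", ["genotype"])
        base.insert(0, "metric", "baseline_power")
        report["coupling"] = pd.concat(
            [peak.rename(columns={"peak_norm_power": "value"}),
             base.rename(columns={"baseline_power": "value"})],
            ignore_index=True,
        )
    return report
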