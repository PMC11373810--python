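"""End-to-end pipeline: ingest -> bouts -> trip split -> randomization -> models.

A run is fully specified by a :class:`RunConfig` (inputs or a synthetic
design, the iteration count, alpha, and one master seed) and produces a run
directory containing the session bout tables, per-session randomization
results, the trip classification, model reports, a headline summary, a
deterministic log, and a manifest with SHA-256 checksums of every output.
Identical config + seed gives byte-identical result files: all per-session
randomization seeds are spawned deterministically from the master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .core import Category, SessionRecord, Stage, ValidationError
from .events import (
    DEFAULT_FORAGING_GAP,
    derive_bouts,
    read_event_log,
    read_session_table,
    write_session_table,
)
from .models import fit_chickrearing_trend, fit_incubation_trend, fit_stage_link
from .randomization import mc_null
from .simulate import StudyDesign, simulate_study
from .trips import ClassificationError, classify_trips


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Union[str, Path]
    seed: int = 0
    n_iter: int = 10_000
    alpha: float = 0.05
    n_boot: int = 10_000
    design: Optional[StudyDesign] = None
    events_csv: Optional[Union[str, Path]] = None
    session_table: Optional[Union[str, Path]] = None
    foraging_gap: int = DEFAULT_FORAGING_GAP

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path, out_dir=None, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {
            k: raw[k]
            for k in ("seed", "n_iter", "alpha", "n_boot", "foraging_gap")
            if k in raw
        }
        inp = raw.get("input", {})
        if "synthetic" in inp:
            syn = dict(inp["synthetic"])
            if "years" in syn:
                syn["years"] = tuple(syn["years"])
            kwargs["design"] = StudyDesign(**syn)
        if "events" in inp:
            kwargs["events_csv"] = inp["events"]
        if "session_table" in inp:
            kwargs["session_table"] = inp["session_table"]
        kwargs["out_dir"] = out_dir or raw.get("out_dir", "nestcoord-run")
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class RunResult:
    out_dir: Path
    sessions: list
    results: pd.DataFrame
    trips: Optional[pd.DataFrame]
    summary: dict
    reports: dict = field(default_factory=dict)


def _child_seed(root: np.random.SeedSequence) -> int:
    return int(root.spawn(1)[0].generate_state(1)[0] % (2**31))


def _load_sessions(config: RunConfig, log: list) -> list[SessionRecord]:
    if config.design is not None:
        design = config.design
        if design.seed is None:
            design = StudyDesign(
                **{**design.__dict__, "seed": config.seed}
            )
        log.append(
            f"input: synthetic study ({design.n_pairs_incubation} incubation pairs, "
            f"{design.n_pairs_chick} chick pairs, years {tuple(design.years)})"
        )
        return simulate_study(design)
    if config.session_table is not None:
        log.append(f"input: session table {config.session_table}")
        return read_session_table(config.session_table)
    if config.events_csv is not None:
        log.append(f"input: event log {config.events_csv}")
        sessions = []
        for se in read_event_log(config.events_csv):
            by_sex = {se.sex[ind]: ind for ind in se.events}
            if set(by_sex) != {"F", "M"}:
                log.append(
                    f"dropped session {se.session_id}: missing partner data "
                    f"(individuals: {sorted(se.events)})"
                )
                continue
            seqs, extrap = {}, {}
            for sex in ("F", "M"):
                ind = by_sex[sex]
                seq, ex = derive_bouts(
                    se.events[ind], se.stage, se.duration, config.foraging_gap
                )
                seqs[sex], extrap[sex] = seq, ex
            sessions.append(
                SessionRecord(
                    session_id=se.session_id,
                    pair_id=se.pair_id,
                    year=se.year,
                    stage=se.stage,
                    phase=se.phase,
                    duration=se.duration,
                    bouts_f=seqs["F"],
                    bouts_m=seqs["M"],
                    extrapolated=extrap,
                )
            )
        return sessions
    raise ValidationError("config needs a synthetic design, event log, or session table")


def _trip_table(sessions: list[SessionRecord]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        if s.stage is not Stage.CHICK_REARING:
            continue
        for sex, seq in (("F", s.bouts_f), ("M", s.bouts_m)):
            for b in seq:
                if b.category is Category.FORAGING and b.food is not False:
                    rows.append(
                        {
                            "session_id": s.session_id,
                            "pair_id": s.pair_id,
                            "year": s.year,
                            "phase": s.phase,
                            "individual_id": f"{s.pair_id}-{sex}",
                            "sex": sex,
                            "start_s": b.start,
                            "end_s": b.end,
                            "duration_h": (b.end - b.start) / 3600.0,
                        }
                    )
    return pd.DataFrame(rows)


def _randomize_sessions(
    sessions, trips: Optional[pd.DataFrame], config: RunConfig, root, log
) -> pd.DataFrame:
    rows = []
    label_lookup = {}
    if trips is not None and not trips.empty:
        for (sid, ind), sub in trips.groupby(["session_id", "individual_id"]):
            label_lookup[(sid, ind)] = [
                lab for _, lab in sorted(zip(sub["start_s"], sub["label"]))
            ]
    for s in sessions:
        seed = _child_seed(root)
        if s.stage is Stage.INCUBATION:
            res = mc_null(
                s.bouts_f, s.bouts_m, n_iter=config.n_iter, rng=seed, mode="activity"
            )
        else:
            lf = label_lookup.get((s.session_id, f"{s.pair_id}-F"), [])
            lm = label_lookup.get((s.session_id, f"{s.pair_id}-M"), [])
            res = mc_null(
                s.bouts_f,
                s.bouts_m,
                n_iter=config.n_iter,
                rng=seed,
                mode="provisioning",
                trip_labels_f=lf,
                trip_labels_m=lm,
            )
        rows.append(
            {
                "session_id": s.session_id,
                "pair_id": s.pair_id,
                "year": s.year,
                "stage": s.stage.value,
                "phase": s.phase,
                "statistic_name": res.statistic,
                "observed_s": res.observed.seconds,
                "observed_prop": res.observed.proportion,
                "expected_s": res.expected,
                "p_value": res.p_value,
                "index": np.nan if res.index is None else res.index,
                "n_iter": res.n_iter,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def _stage_link_table(results: pd.DataFrame, log: list) -> Optional[pd.DataFrame]:
    """Per-pair wide table for the cross-stage models, first study year only.

    Incubation phases are ranked within the year by days before hatching
    (largest = early); only pairs with all three incubation sessions and
    both chick-rearing sessions are kept (complete cases).
    """
    if results.empty:
        return None
    year0 = int(results["year"].min())
    inc = results[
        (results["stage"] == Stage.INCUBATION.value) & (results["year"] == year0)
    ].copy()
    chick = results[
        (results["stage"] == Stage.CHICK_REARING.value) & (results["year"] == year0)
    ].copy()
    if inc.empty or chick.empty:
        log.append("stage_link: skipped (need both stages in the first year)")
        return None
    rows = []
    for pair, sub in inc.groupby("pair_id"):
        phases = sub.sort_values("phase", ascending=False)
        if len(phases) != 3:
            continue
        csub = chick[chick["pair_id"] == pair]
        early_i = csub[csub["phase"] == "EARLY"]["index"]
        mid_i = csub[csub["phase"] == "MID"]["index"]
        if early_i.empty or mid_i.empty:
            continue
        obs = phases["observed_s"].to_numpy()
        rows.append(
            {
                "pair_id": pair,
                "early_inc": obs[0],
                "mid_inc": obs[1],
                "late_inc": obs[2],
                "chick_index_early": float(early_i.iloc[0]),
                "chick_index_mid": float(mid_i.iloc[0]),
            }
        )
    if not rows:
        log.append("stage_link: skipped (no complete-case pairs)")
        return None
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write the run directory.

    Stages: load (or simulate) sessions; classify chick-rearing trips;
    randomize every session; fit the three model families where their data
    prerequisites are met (a model whose prerequisites fail is skipped with
    a logged reason); write results, reports, summary, log, and manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"config: seed={config.seed} n_iter={config.n_iter} "
        f"alpha={config.alpha} n_boot={config.n_boot}"
    ]
    root = np.random.SeedSequence(config.seed)

    try:
        sessions = _load_sessions(config, log)
    except Exception as exc:
        raise PipelineError(f"stage ingest: {exc}") from exc
    if not sessions:
        raise PipelineError("stage ingest: no usable sessions")
    log.append(f"loaded {len(sessions)} sessions")

    # trip classification (chick-rearing sessions only)
    trips = None
    try:
        trip_rows = _trip_table(sessions)
        if not trip_rows.empty:
            trips = trip_rows.copy()
            trips["label"] = ""
            trips["threshold_h"] = np.nan
            for (phase, year), idx in trips.groupby(["phase", "year"]).groups.items():
                try:
                    split = classify_trips(trips.loc[idx, "duration_h"].to_numpy())
                except ClassificationError as exc:
                    raise PipelineError(
                        f"stage trip_split [{phase} {year}]: {exc}"
                    ) from exc
                trips.loc[idx, "label"] = [l.value for l in split.labels]
                trips.loc[idx, "threshold_h"] = split.threshold
                log.append(
                    f"trip split {phase} {year}: threshold {split.threshold:.2f} h "
                    f"({split.n_short} short, {split.n_long} long)"
                )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage trip_split: {exc}") from exc

    try:
        results = _randomize_sessions(sessions, trips, config, root, log)
    except Exception as exc:
        raise PipelineError(f"stage randomization: {exc}") from exc

    # models
    reports: dict = {}
    try:
        inc = results[results["stage"] == Stage.INCUBATION.value]
        if len(inc) >= 6 and inc["pair_id"].nunique() >= 2 and inc["phase"].nunique() >= 2:
            df = inc.rename(columns={"observed_s": "coordination_s"})
            reports["incubation_trend"] = fit_incubation_trend(df)
        else:
            log.append("incubation_trend: skipped (insufficient data)")
        chick = results[results["stage"] == Stage.CHICK_REARING.value].dropna(
            subset=["index"]
        )
        if len(chick) >= 6 and chick["phase"].nunique() >= 2:
            df = chick.rename(columns={"index": "chick_index"})
            reports["chickrearing_trend"] = fit_chickrearing_trend(df)
        else:
            log.append("chickrearing_trend: skipped (insufficient data)")
        wide = _stage_link_table(results, log)
        if wide is not None and len(wide) >= 6:
            reports.update(
                fit_stage_link(
                    wide, n_boot=config.n_boot, rng=np.random.default_rng(_child_seed(root))
                )
            )
        elif wide is not None:
            log.append("stage_link: skipped (fewer than 6 complete-case pairs)")
    except Exception as exc:
        raise PipelineError(f"stage models: {exc}") from exc

    # headline summary
    summary: dict = {"seed": config.seed, "n_iter": config.n_iter, "alpha": config.alpha}
    inc = results[results["stage"] == Stage.INCUBATION.value]
    if not inc.empty:
        summary["incubation"] = {
            "n_sessions": int(len(inc)),
            "mean_opposite_proportion": float(inc["observed_prop"].mean()),
            "iqr_opposite_proportion": [
                float(inc["observed_prop"].quantile(0.25)),
                float(inc["observed_prop"].quantile(0.75)),
            ],
            "fraction_coordinated": float((inc["p_value"] < config.alpha).mean()),
        }
    chick = results[results["stage"] == Stage.CHICK_REARING.value]
    if not chick.empty:
        summary["chick_rearing"] = {
            "n_sessions": int(len(chick)),
            "mean_shortlong_proportion": float(chick["observed_prop"].mean()),
            "fraction_coordinated": float((chick["p_value"] < config.alpha).mean()),
            "mean_index": float(chick["index"].mean()),
        }
        if trips is not None:
            summary["trip_thresholds_h"] = {
                f"{phase}_{year}": float(sub["threshold_h"].iloc[0])
                for (phase, year), sub in trips.groupby(["phase", "year"])
            }

    # write everything
    try:
        from .plots import save_summary_plots

        save_summary_plots(results, out / "figures")
        write_session_table(sessions, out / "sessions.csv")
        results.to_csv(out / "randomization_results.csv", index=False)
        if trips is not None:
            trips.to_csv(out / "trips.csv", index=False)
        with open(out / "model_reports.json", "w", encoding="utf-8") as fh:
            json.dump(
                {k: r.to_dict() for k, r in reports.items()},
                fh,
                indent=2,
                sort_keys=True,
                default=float,
            )
        with open(out / "model_reports.txt", "w", encoding="utf-8") as fh:
            fh.write("\n\n".join(r.summary() for r in reports.values()))
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
        manifest = {
            p.relative_to(out).as_posix(): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise PipelineError(f"stage write: {exc}") from exc

    return RunResult(
        out_dir=out,
        sessions=sessions,
        results=results,
        trips=trips,
        summary=summary,
        reports=reports,
    )
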