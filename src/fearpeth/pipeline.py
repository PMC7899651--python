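"""Config-driven pipeline tying the stages into one reproducible run.

Stages (each also a CLI subcommand):

``simulate``
    Realize the cohort design: per group, a session timeline, a behavior
    trace and unit spike trains, written as CSV.
``score-freezing``
    Freezing percentage per epoch and freeze onset/cessation events.
``classify``
    Peri-event z-score profiles and CS-ON / Freeze-ON / Freeze-OFF calls.
``compare``
    Group summaries, pairwise Fisher exact tests, and a paired t-test on
    baseline-vs-post z of responsive units.

Stage seeds are split from the master seed as
``SeedSequence([master_seed, stage_index]).generate_state(1)[0] % 2**31``
so any stage can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .behavior import extract_freeze_events, score_freezing
from .perievent import (
    ClassifierParams,
    PerieventMatrix,
    align_and_bin,
    classify_all,
    mean_rate,
    zscore_profile,
)
from .protocol import EventLabel, ProtocolKind
from .stats import paired_t, pairwise_comparisons, summarize_groups
from .synthetic import BehaviorModelParams, CohortDesign, GroupDesign, simulate_cohort

__all__ = ["PipelineConfig", "run_all", "stage_simulate", "stage_score_freezing",
           "stage_classify", "stage_compare"]

log = logging.getLogger("fearpeth")

#: stage name -> index used in the seed derivation
STAGE_INDEX = {"simulate": 0, "score-freezing": 1, "classify": 2, "compare": 3}

_ALLOWED_TOP = {"seed", "output_dir", "protocol", "classifier", "simulation", "sampling"}


def stage_seed(master_seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([master_seed, STAGE_INDEX[stage]]).generate_state(1)[0] % 2**31)


def _kwargs_for(cls, section: dict, where: str) -> dict:
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return dict(section)


class PipelineConfig:
    """Validated pipeline configuration loaded from YAML.

    Sections: ``protocol`` (kind), ``classifier`` (ClassifierParams
    fields), ``simulation`` (groups + behavior), ``sampling``
    (freezing ``sample_interval``), plus top-level ``seed`` and
    ``output_dir``.  Unknown keys anywhere are rejected.
    """

    def __init__(self, doc: dict, base_dir: Path = Path(".")):
        unknown = set(doc) - _ALLOWED_TOP
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        self.raw = doc
        self.seed = int(doc.get("seed", 0))
        self.output_dir = base_dir / doc.get("output_dir", "fearpeth_out")

        proto = dict(doc.get("protocol", {}))
        kind = proto.pop("kind", "RETRIEVAL")
        if proto:
            raise ValueError(f"unknown key(s) in protocol: {sorted(proto)}")
        self.protocol_kind = ProtocolKind(kind)

        self.classifier = ClassifierParams(
            **_kwargs_for(ClassifierParams, doc.get("classifier", {}), "classifier")
        )

        sim = dict(doc.get("simulation", {}))
        groups = sim.pop("groups", [])
        behavior = sim.pop("behavior", {})
        if sim:
            raise ValueError(f"unknown key(s) in simulation: {sorted(sim)}")
        self.behavior_params = BehaviorModelParams(
            **_kwargs_for(BehaviorModelParams, behavior, "simulation.behavior")
        )
        self.groups = tuple(
            GroupDesign(**_kwargs_for(GroupDesign, g, "simulation.groups[]")) for g in groups
        )

        sampling = dict(doc.get("sampling", {}))
        self.sample_interval = float(sampling.pop("sample_interval", 5.0))
        if sampling:
            raise ValueError(f"unknown key(s) in sampling: {sorted(sampling)}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text()) or {}
        return cls(doc, base_dir=path.parent)

    def cohort_design(self) -> CohortDesign:
        return CohortDesign(
            groups=self.groups,
            behavior_params=self.behavior_params,
            protocol_kind=self.protocol_kind,
            seed=stage_seed(self.seed, "simulate"),
        )


def _group_dirs(cfg: PipelineConfig) -> dict[str, Path]:
    return {g.group_label: cfg.output_dir / g.group_label for g in cfg.groups}


def _timed(name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("stage %s finished in %.2f s", name, time.perf_counter() - self.t0)

    return _T()


def stage_simulate(cfg: PipelineConfig, manifest: io.RunManifest) -> None:
    """Generate and write the synthetic cohort."""
    with _timed("simulate"):
        cohort = simulate_cohort(cfg.cohort_design())
        outputs = []
        for gd in cohort.groups:
            d = cfg.output_dir / gd.group_label
            d.mkdir(parents=True, exist_ok=True)
            io.write_timeline(d / "timeline.csv", gd.timeline, d / "protocol.yaml")
            io.write_bouts(d / "bouts.csv", gd.behavior)
            io.write_spikes(
                d / "spikes.csv",
                {s.unit_id: _as_train(s) for s in gd.spikes},
            )
            truth = [
                {"unit_id": uid, "label": ";".join(labels), "multiplier": mult}
                for uid, labels, mult in (
                    (u.unit_id, gd.truth[u.unit_id],
                     u.modulations[0].multiplier if u.modulations else 1.0)
                    for u in gd.units
                )
            ]
            pd.DataFrame(truth, columns=["unit_id", "label", "multiplier"]).to_csv(
                d / "truth.csv", index=False
            )
            outputs += [str(d / f) for f in
                        ("timeline.csv", "protocol.yaml", "bouts.csv", "spikes.csv", "truth.csv")]
        manifest.add_stage("simulate", inputs=[], outputs=outputs)


def _as_train(s):
    from .perievent import SpikeTrain

    return SpikeTrain(unit_id=s.unit_id, timestamps=s.timestamps, session_dur=s.session_dur)


def stage_score_freezing(cfg: PipelineConfig, manifest: io.RunManifest) -> None:
    """Score freezing and extract freeze events for every group."""
    with _timed("score-freezing"):
        exclusions: list[str] = []
        outputs, inputs = [], []
        for g, d in _group_dirs(cfg).items():
            timeline = io.read_timeline(d / "timeline.csv", d / "protocol.yaml")
            trace = io.read_bouts(d / "bouts.csv", timeline.total_dur)
            summary = score_freezing(trace, timeline, cfg.sample_interval)
            pre = cfg.classifier.n_baseline_bins * cfg.classifier.bin_width + 1.0
            events = extract_freeze_events(trace, timeline, pre_window=pre)
            io.write_freezing_summary(d / "freezing_summary.csv", summary)
            io.write_freeze_events(d / "freeze_events.csv", events)
            exclusions += [f"{g}: {m}" for m in events.exclusion_log]
            inputs += [str(d / "timeline.csv"), str(d / "bouts.csv")]
            outputs += [str(d / "freezing_summary.csv"), str(d / "freeze_events.csv")]
        manifest.add_stage("score-freezing", inputs=inputs, outputs=outputs)
        manifest.exclusions["freeze_events"] = exclusions


def stage_classify(cfg: PipelineConfig, manifest: io.RunManifest) -> None:
    """Classify every unit's responsiveness for all three alignments."""
    with _timed("classify"):
        exclusions: list[str] = []
        outputs, inputs = [], []
        for g, d in _group_dirs(cfg).items():
            timeline = io.read_timeline(d / "timeline.csv", d / "protocol.yaml")
            spikes = io.read_spikes(d / "spikes.csv", session_dur=timeline.total_dur)
            ev = pd.read_csv(d / "freeze_events.csv")
            from .behavior import FreezeEventSeries

            freeze = FreezeEventSeries(
                onsets=tuple(ev.loc[ev["type"] == "onset", "time_s"]),
                cessations=tuple(ev.loc[ev["type"] == "cessation", "time_s"]),
            )
            calls = classify_all(spikes, timeline, freeze, cfg.classifier)
            io.write_classification(d / "classification.csv", calls)
            zrows = []
            cs_times = timeline.times(EventLabel.CS_ON)
            freeze_params = ClassifierParams(
                **{**_params_dict(cfg.classifier), "baseline_offset": 1.0}
            )
            for uid, train in spikes.items():
                for label, (times, p) in {
                    "CS_ON": (cs_times, cfg.classifier),
                    "FREEZE_ON": (np.asarray(freeze.onsets), freeze_params),
                    "FREEZE_OFF": (np.asarray(freeze.cessations), freeze_params),
                }.items():
                    if times.size == 0:
                        continue
                    mat = align_and_bin(train, times, p)
                    if mat.counts.shape[0] == 0:
                        continue
                    prof = zscore_profile(
                        PerieventMatrix(uid, label, mat.counts, mat.bin_edges), p
                    )
                    if prof.degenerate:
                        continue
                    for b, z in zip(p.bin_edges[:-1], prof.z):
                        zrows.append(
                            {"unit_id": uid, "label": label,
                             "bin_left_s": round(float(b), 6), "z": z}
                        )
                exclusions += [f"{g}/{uid}: {label}: {why}"
                               for label, why in calls[uid].skipped.items()]
            pd.DataFrame(zrows, columns=["unit_id", "label", "bin_left_s", "z"]).to_csv(
                d / "zprofiles.csv", index=False
            )
            rates = [{"unit_id": uid, "mean_rate_hz": mean_rate(tr)}
                     for uid, tr in spikes.items()]
            pd.DataFrame(rates, columns=["unit_id", "mean_rate_hz"]).to_csv(
                d / "unit_rates.csv", index=False
            )
            inputs += [str(d / "spikes.csv"), str(d / "freeze_events.csv")]
            outputs += [str(d / "classification.csv"), str(d / "zprofiles.csv"),
                        str(d / "unit_rates.csv")]
        manifest.add_stage("classify", inputs=inputs, outputs=outputs)
        manifest.exclusions["classification"] = exclusions


def _params_dict(p: ClassifierParams) -> dict:
    return {f.name: getattr(p, f.name) for f in dc_fields(ClassifierParams)}


def stage_compare(cfg: PipelineConfig, manifest: io.RunManifest) -> None:
    """Group summaries, pairwise Fisher tests, paired baseline-vs-post t."""
    with _timed("compare"):
        dirs = _group_dirs(cfg)
        calls_df = {g: io.read_classification(d / "classification.csv") for g, d in dirs.items()}
        zprof = {g: pd.read_csv(d / "zprofiles.csv") for g, d in dirs.items()}
        sum_rows, cmp_rows, t_rows = [], [], []
        for label in ("CS_ON", "FREEZE_ON", "FREEZE_OFF"):
            counts = {}
            for g, df in calls_df.items():
                sub = df[(df["label"] == label) & (df["responsive"].astype(str) != "")]
                counts[g] = (int((sub["responsive"].astype(str) == "True").sum()), len(sub))
            counts = {g: c for g, c in counts.items() if c[1] > 0}
            if not counts:
                continue
            summaries = summarize_groups(counts, event_label=label)
            for s in summaries:
                sum_rows.append({"group": s.group_label, "label": label,
                                 "n_responsive": s.n_responsive, "n_total": s.n_total,
                                 "percent": s.percent})
            for row in pairwise_comparisons(summaries):
                cmp_rows.append({**row, "label": label})
            base, post = _paired_z(calls_df, zprof, label)
            if len(base) >= 2:
                res = paired_t(base, post)
                t_rows.append({"label": label, "n": len(base), "t": res.t, "df": res.df,
                               "p": "" if res.p is None else res.p,
                               "degenerate": res.degenerate})
        cfg.output_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(sum_rows, columns=["group", "label", "n_responsive", "n_total", "percent"]
                     ).to_csv(cfg.output_dir / "group_summary.csv", index=False)
        pd.DataFrame(cmp_rows, columns=["label", "group_a", "group_b", "a", "b", "c", "d",
                                        "p_two_sided"]
                     ).to_csv(cfg.output_dir / "comparisons.csv", index=False)
        pd.DataFrame(t_rows, columns=["label", "n", "t", "df", "p", "degenerate"]
                     ).to_csv(cfg.output_dir / "paired_t.csv", index=False)
        manifest.add_stage(
            "compare",
            inputs=[str(d / "classification.csv") for d in dirs.values()],
            outputs=[str(cfg.output_dir / f)
                     for f in ("group_summary.csv", "comparisons.csv", "paired_t.csv")],
        )


def _paired_z(calls_df, zprof, label):
    """Baseline vs post mean-z pairs across responsive units (all groups).

    Baseline = mean z over the baseline bins, post = mean z over the
    response-window bins of each responsive unit's profile.  This pairing
    is the pipeline's documented default; any (baseline, post) pairing can
    be fed to :func:`fearpeth.stats.paired_t` directly.
    """
    base, post = [], []
    for g, df in calls_df.items():
        resp = df[(df["label"] == label) & (df["responsive"].astype(str) == "True")]["unit_id"]
        zp = zprof[g]
        for uid in resp:
            sub = zp[(zp["unit_id"] == uid) & (zp["label"] == label)].sort_values("bin_left_s")
            if len(sub) == 0:
                continue
            z = sub["z"].to_numpy()
            base.append(float(z[:10].mean()))
            post.append(float(z[-5:].mean()))
    return np.array(base), np.array(post)


def run_all(config_path) -> io.RunManifest:
    """Run simulate → score-freezing → classify → compare from one config."""
    cfg = PipelineConfig.from_file(config_path)
    manifest = io.RunManifest.new(cfg.raw, cfg.seed)
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    stage_simulate(cfg, manifest)
    stage_score_freezing(cfg, manifest)
    stage_classify(cfg, manifest)
    stage_compare(cfg, manifest)
    manifest.write(cfg.output_dir / "manifest.json")
    return manifest
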