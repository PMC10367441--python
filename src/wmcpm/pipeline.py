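"""End-to-end study pipeline: behavioral scoring and exclusions, confound
regression, connectivity, node harmonization, network strength, and the
statistical analyses, with machine-checkable exclusion logging.

Stage order is fixed: behavior -> denoise -> connectome -> harmonize ->
strength -> stats. Run usability is decided once, by the behavioral
accuracy rule, and passed to the connectome stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import connectome as conn
from . import denoise as dn
from . import stats as st
from . import strength as stren
from . import synth
from .core import ConnectivityMatrix, NetworkMask, NodeTimeSeries


@dataclass
class PipelineConfig:
    """Paths, thresholds, and method choices for one pipeline run."""

    data_dir: str = "."
    output_dir: str = "results"
    high_mask: str = "masks/high_wm_mask.tsv"
    low_mask: str = "masks/low_wm_mask.tsv"
    repetition_time: float = 1.0
    atlas_size: int = 268
    run_accuracy_cutoff: float = beh.RUN_ACCURACY_CUTOFF
    mean_fd_cutoff_mm: float = dn.MEAN_FD_EXCLUSION_MM
    spike_fd_mm: float = dn.SPIKE_FD_MM
    cesd_cutoff: int = beh.CESD_ELIGIBILITY_CUTOFF
    highpass_hz: float = dn.DEFAULT_HIGHPASS_HZ
    strength_statistic: str = "mean"
    df_method: str = "between-within"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("run_accuracy_cutoff", "mean_fd_cutoff_mm", "spike_fd_mm", "highpass_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and subject."""

    def __init__(self, stage: str, subject: str | None, message: str):
        self.stage = stage
        self.subject = subject
        super().__init__(f"[{stage}] subject={subject}: {message}")


@dataclass
class ExclusionLog:
    records: list = field(default_factory=list)

    def log(self, stage: str, subject: str, rule: str, action: str) -> None:
        self.records.append(
            {"stage": stage, "subject": subject, "rule": rule, "action": action}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["stage", "subject", "rule", "action"]
        )


# ---------------------------------------------------------------------------
# dataset simulation to files


def simulate_study(
    sim_config: synth.SimulationConfig,
    out_dir,
    n_runs: int = 2,
    write_time_series: bool = True,
) -> dict:
    """Generate and write a complete file-based synthetic study.

    Per subject: a target correlation structure with planted mask-strength
    signal, ``n_runs`` of node time series and confounds, N-back trials
    whose 2-back ability tracks combined strength, ERC trials, and DERS
    items. Returns the planted ground truth.
    """
    out = Path(out_dir)
    for sub in ("timeseries", "confounds", "masks", "behavior"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sim_config.seed)

    high, low = synth.gen_masks(
        sim_config.n_nodes,
        sim_config.n_high_edges,
        sim_config.n_low_edges,
        int(rng.integers(2**31)),
    )
    high.write_edgelist(out / "masks" / "high_wm_mask.tsv")
    low.write_edgelist(out / "masks" / "low_wm_mask.tsv")

    matrices, _, _ = synth.gen_cohort(
        dataclasses.replace(sim_config, seed=int(rng.integers(2**31))), masks=(high, low)
    )
    subjects, truth_rows = [], []
    for m in matrices:
        target = synth.nearest_correlation(np.tanh(m.values))
        r_target = target.copy()
        np.fill_diagonal(r_target, 0.0)
        target_cm = ConnectivityMatrix(
            values=r_target, scale="r", node_ids=m.node_ids, subject=m.subject
        )
        true_scores = stren.strength_scores(conn.fisher_z(target_cm), high, low)
        truth_rows.append(
            {
                "subject": m.subject,
                "high": true_scores.high,
                "low": true_scores.low,
                "combined": true_scores.combined,
            }
        )
        subjects.append((m.subject, target))

    truth = pd.DataFrame(truth_rows)
    combined = truth["combined"].to_numpy()
    combined_c = combined - combined.mean()
    scale = combined_c.std(ddof=1) or 1.0

    if write_time_series:
        for subject, target in subjects:
            for run in range(1, n_runs + 1):
                ts = synth.gen_time_series(
                    target, sim_config.n_timepoints, seed=int(rng.integers(2**31))
                )
                pd.DataFrame(
                    ts, columns=[str(i) for i in range(1, sim_config.n_nodes + 1)]
                ).to_csv(out / "timeseries" / f"{subject}_run-{run}_timeseries.tsv", sep="\t", index=False)
                conf = synth.gen_confounds(
                    sim_config.n_timepoints,
                    sim_config.repetition_time,
                    sim_config.spike_rate,
                    seed=int(rng.integers(2**31)),
                )
                conf.to_csv(out / "confounds" / f"{subject}_run-{run}_confounds.tsv", sep="\t", index=False)

    # behavioral records: 2-back ability follows combined strength
    ability = {"2-back": 1.5 * combined_c / scale}
    records = synth.gen_behavioral_cohort(
        sim_config.n_subjects,
        moderator=combined_c,
        nback_ability=ability,
        seed=int(rng.integers(2**31)),
    )
    records["nback"].to_csv(out / "behavior" / "nback_trials.csv", index=False)
    records["erc"].to_csv(out / "behavior" / "erc_trials.csv", index=False)
    records["items"].to_csv(out / "behavior" / "ders_items.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    return {"truth": truth, "masks": (high, low)}


# ---------------------------------------------------------------------------
# pipeline stages


def _behavior_stage(data_dir: Path, config: PipelineConfig, log: ExclusionLog) -> pd.DataFrame:
    nback = pd.read_csv(data_dir / "behavior" / "nback_trials.csv")
    erc = pd.read_csv(data_dir / "behavior" / "erc_trials.csv")
    items_path = data_dir / "behavior" / "ders_items.csv"
    items = pd.read_csv(items_path) if items_path.exists() else None

    rows = []
    for subject, sub_trials in nback.groupby("subject"):
        run_summaries = {
            run: beh.score_nback_run(run_trials)
            for run, run_trials in sub_trials.groupby("run")
        }
        usable, excluded = beh.apply_nback_exclusions(
            run_summaries, cutoff=config.run_accuracy_cutoff
        )
        for run, summary in run_summaries.items():
            if run not in usable:
                log.log(
                    "behavior", subject,
                    f"run mean accuracy {summary['run_accuracy']:.3f} <= {config.run_accuracy_cutoff}",
                    f"excluded run {run}",
                )
        if excluded:
            log.log("behavior", subject, "below-cutoff accuracy on all runs", "excluded subject")
            continue
        summary = beh.nback_subject_summary([run_summaries[r] for r in usable])
        row = {
            "subject": subject,
            "usable_runs": ",".join(str(r) for r in usable),
            "acc_0back": summary["0-back"]["accuracy"],
            "acc_2back": summary["2-back"]["accuracy"],
            "rt_0back": summary["0-back"]["mean_rt"],
            "rt_2back": summary["2-back"]["mean_rt"],
        }
        sub_erc = erc[erc["subject"] == subject]
        if len(sub_erc):
            scores = beh.score_erc(sub_erc)
            row.update(
                accept_overall=scores["overall_pct"],
                accept_low=scores["low_pct"],
                accept_high=scores["high_pct"],
            )
        if items is not None:
            sub_items = items[items["subject"] == subject].sort_values("item")
            if len(sub_items) == beh.INSTRUMENTS["DERS"].n_items:
                row["ders_total"] = beh.score_scale("DERS", sub_items["response"].to_numpy())
        rows.append(row)
    if not rows:
        raise StageError("behavior", None, "no subjects survived behavioral exclusions")
    return pd.DataFrame(rows)


def _connectome_stage(
    data_dir: Path,
    config: PipelineConfig,
    scores: pd.DataFrame,
    log: ExclusionLog,
) -> tuple[list[ConnectivityMatrix], pd.Series, tuple[int, ...], dict]:
    """Denoise usable runs, build z-matrices, harmonize node coverage."""
    matrices, mean_fds, missing_sets, kept_subjects = [], {}, [], []
    for _, row in scores.iterrows():
        subject = row["subject"]
        usable = [r for r in str(row["usable_runs"]).split(",") if r]
        run_mats, run_fds, sub_missing = [], [], set()
        for run in usable:
            ts_path = data_dir / "timeseries" / f"{subject}_run-{run}_timeseries.tsv"
            conf_path = data_dir / "confounds" / f"{subject}_run-{run}_confounds.tsv"
            if not ts_path.exists():
                raise StageError("denoise", subject, f"missing time series {ts_path.name}")
            ts = NodeTimeSeries.from_file(
                ts_path, repetition_time=config.repetition_time, subject=subject, run=run
            )
            confounds = dn.load_confounds(conf_path)
            if len(confounds) != ts.n_timepoints:
                raise StageError(
                    "denoise", subject,
                    f"confounds have {len(confounds)} rows, run has {ts.n_timepoints}",
                )
            fd = confounds["framewise_displacement"].to_numpy()
            spikes = dn.flag_spikes(fd, config.spike_fd_mm)
            design = dn.build_design(
                confounds, spikes, config.highpass_hz, config.repetition_time
            )
            raw_sd = ts.values.std(axis=0)
            clean = dn.regress_confounds(ts.values, design)
            # a node is missing when its parcel signal is flat (zero
            # coverage or zero variance) in any run
            dead = {ts.node_ids[i] for i in np.flatnonzero(raw_sd == 0)}
            sub_missing |= dead
            keep = [i for i, n in enumerate(ts.node_ids) if n not in dead]
            cleaned_ts = NodeTimeSeries(
                values=clean[:, keep],
                node_ids=tuple(ts.node_ids[i] for i in keep),
                repetition_time=ts.repetition_time,
                subject=subject,
                run=run,
            )
            run_mats.append(conn.correlation_matrix(cleaned_ts))
            run_fds.append(fd.mean())
        mean_fd, excluded = dn.motion_gate(np.array(run_fds), config.mean_fd_cutoff_mm)
        if excluded:
            log.log(
                "denoise", subject,
                f"mean FD {mean_fd:.3f} mm >= {config.mean_fd_cutoff_mm}",
                "excluded subject",
            )
            continue
        if sub_missing:
            log.log(
                "connectome", subject,
                f"zero-variance node(s) {sorted(sub_missing)}",
                "flagged missing nodes",
            )
            common = set(run_mats[0].node_ids)
            for m in run_mats[1:]:
                common &= set(m.node_ids)
            kept_ids = tuple(sorted(common))
            aligned = []
            for m in run_mats:
                idx = np.array([m.index_of(i) for i in kept_ids])
                aligned.append(
                    ConnectivityMatrix(
                        values=m.values[np.ix_(idx, idx)], scale="r",
                        node_ids=kept_ids, subject=subject,
                    )
                )
            run_mats = aligned
        avg = conn.average_runs(run_mats)
        matrices.append(conn.fisher_z(avg))
        mean_fds[subject] = mean_fd
        missing_sets.append(sub_missing)
        kept_subjects.append(subject)

    if not matrices:
        raise StageError("connectome", None, "no usable subjects")
    harmonized, kept_nodes = conn.harmonize_nodes(matrices, missing_sets)
    info = {
        "n_subjects": len(harmonized),
        "n_nodes_original": config.atlas_size,
        "n_nodes_kept": len(kept_nodes),
    }
    return harmonized, pd.Series(mean_fds, name="mean_fd"), kept_nodes, info


def _stats_stage(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Correlation battery, moderation models, simple slopes, power."""
    pairs = []
    for x in ("combined", "high", "low"):
        for y in ("acc_2back", "accept_overall", "ders_total"):
            if y in table.columns and table[y].notna().sum() >= 4:
                pairs.append((x, y))
    if "mean_fd" in table.columns:
        for y in ("acc_2back", "accept_overall", "ders_total"):
            if y in table.columns and table[y].notna().sum() >= 4:
                pairs.append(("mean_fd", y))
    battery = st.correlation_battery(table, pairs)

    moderation = {}
    for moderator in ("combined", "high", "low", "acc_2back"):
        if not {"accept_low", "accept_high"} <= set(table.columns):
            break
        sub = table.dropna(subset=["accept_low", "accept_high", moderator])
        long = st.prepare_moderation_table(
            sub["accept_low"].to_numpy(),
            sub["accept_high"].to_numpy(),
            sub[moderator].to_numpy(),
            subjects=list(sub["subject"]),
        )
        fit = st.fit_moderation(long, df_method=config.df_method)
        slopes = st.simple_slopes(fit)
        moderation[moderator] = {
            "terms": {
                name: dataclasses.asdict(t) for name, t in fit.terms.items()
            },
            "random_intercept_var": fit.random_intercept_var,
            "residual_var": fit.residual_var,
            "n_subjects": fit.n_subjects,
            "simple_slopes": [dataclasses.asdict(s) for s in slopes],
        }

    n = len(table)
    power = {
        "a_priori_n_r37": st.power_n_for_r(0.37, 0.05, 0.80).answer,
        "min_detectable_r": st.min_detectable_r(n, 0.05, 0.80).answer,
        "min_detectable_f": st.min_detectable_f(n, n_predictors=3, test_df=1).answer,
    }
    return {"correlations": battery, "moderation": moderation, "power": power}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage over a file-based dataset and emit the report."""
    data_dir = Path(config.data_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = ExclusionLog()

    nback_path = data_dir / "behavior" / "nback_trials.csv"
    if not nback_path.exists():
        raise StageError("behavior", None, f"missing {nback_path}")
    n_enrolled = pd.read_csv(nback_path)["subject"].nunique()

    scores = _behavior_stage(data_dir, config, log)
    matrices, mean_fd, kept_nodes, node_info = _connectome_stage(
        data_dir, config, scores, log
    )

    high = NetworkMask.from_edgelist(
        data_dir / config.high_mask, "high", config.atlas_size
    )
    low = NetworkMask.from_edgelist(data_dir / config.low_mask, "low", config.atlas_size)
    high_r, n_high = conn.restrict_mask(high, kept_nodes)
    low_r, n_low = conn.restrict_mask(low, kept_nodes)

    strengths = stren.scores_frame(
        [
            stren.strength_scores(m, high_r, low_r, statistic=config.strength_statistic)
            for m in matrices
        ]
    )
    table = scores.merge(strengths, on="subject", how="inner")
    table = table.merge(mean_fd.rename_axis("subject").reset_index(), on="subject")

    results = _stats_stage(table, config)

    report = {
        "subject_flow": {
            "enrolled": int(n_enrolled),
            "after_behavior": int(len(scores)),
            "analyzed": int(len(table)),
        },
        "nodes": dict(node_info),
        "masks": {
            "high_edges_original": high.n_edges,
            "low_edges_original": low.n_edges,
            "high_edges_after_restriction": n_high,
            "low_edges_after_restriction": n_low,
        },
        "exclusions": log.records,
        "power": results["power"],
        "moderation": results["moderation"],
        # hash the analytic settings only, so reports from the same
        # dataset and parameters match regardless of where they are written
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    k: v
                    for k, v in dataclasses.asdict(config).items()
                    if k not in ("data_dir", "output_dir")
                },
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
    }

    table.to_csv(out_dir / "subject_table.csv", index=False)
    results["correlations"].to_csv(out_dir / "correlations.csv", index=False)
    log.to_frame().to_csv(out_dir / "exclusions.csv", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["subject_table"] = table
    report["correlations"] = results["correlations"]
    return report
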