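"""The label-efficiency comparison protocol: SSL fine-tuning vs. supervised.

For one subject the protocol is:

1. unit-scale the recording and pre-train the forecaster on all pretext pairs;
2. per questionnaire item, tile the labelled segments into windows, hold out a
   fixed test set, and form a labelled training pool;
3. per label budget and bootstrap resample, draw the budget from the pool and
   train two models **on the identical draw**: the transferred-and-frozen
   model with a fine-tuned dense head (``ssl``) and the identically
   architected fully trainable control (``supervised``);
4. score both on the fixed test set with RMSE, one tidy row per
   subject × question × method × budget × resample.

Pairing is the protocol's backbone: both arms of every comparison consume
byte-identical training windows and the same test set (each row carries a
hash of the sampled index list so this is checkable after the fact). The
whole protocol is deterministic given its seed lists.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_io import SubjectDataset, write_results
from .modeling import (
    DownstreamArchitecture,
    PretextArchitecture,
    Sequential,
    TrainConfig,
    build_pretext_model,
    downstream_train_config,
    evaluate_regressor,
    extract_frozen_features,
    finetune,
    pretext_train_config,
    pretrain,
    train_supervised,
    transfer_and_freeze,
    windows_to_arrays,
)
from .simulate import ValidationError
from .windowing import WindowingParams, make_labeled_windows, make_pretext_pairs, normalize_recording, split_train_test

__all__ = [
    "ProtocolConfig",
    "ComparisonResult",
    "LabelEfficiencyReport",
    "StudyResult",
    "default_study_protocol",
    "label_efficiency_study",
    "stable_seed",
    "pretrain_subject",
    "run_comparison",
    "label_efficiency_curve",
    "summarize",
]


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed derived from string-able parts (CRC-32)."""
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class ProtocolConfig:
    """Comparison-protocol settings.

    ``seeds`` drives the bootstrap draws (one per resample). ``pool_size``
    caps the labelled training pool (windows beyond it are never sampled), so
    budgets are interpretable as a fraction of a fixed pool.
    ``sample_with_replacement=False`` takes each bootstrap draw without
    replacement — five independent samples of distinct windows; the
    with-replacement variant is selectable.
    """

    label_budget: int = 10
    n_resamples: int = 5
    budget_sweep: tuple[int, ...] = (10, 20, 30, 50, 75, 100)
    test_fraction: float = 0.2
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    pool_size: int | None = 100
    split_mode: str = "random"
    split_seed: int = 7
    sample_with_replacement: bool = False
    labeled_stride: int | None = None

    def __post_init__(self) -> None:
        if self.label_budget < 1:
            raise ValidationError("label_budget must be >= 1")
        if self.n_resamples < 1:
            raise ValidationError("n_resamples must be >= 1")
        if len(self.seeds) < self.n_resamples:
            raise ValidationError(
                f"need at least {self.n_resamples} seeds, got {len(self.seeds)}"
            )
        if list(self.budget_sweep) != sorted(self.budget_sweep):
            raise ValidationError("budget_sweep must be sorted ascending")


@dataclass
class ComparisonResult:
    """Tidy per-row RMSE table for one or more subjects.

    Columns: subject_id, question_id, method, budget, resample, rmse,
    draw_hash (hash of the sampled pool indices — equal across the two
    methods of one paired cell by construction).
    """

    rows: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Mean and sd of RMSE per subject × question × method × budget."""
        return (
            self.rows.groupby(["subject_id", "question_id", "method", "budget"])["rmse"]
            .agg(mean_rmse="mean", sd_rmse="std")
            .reset_index()
        )

    def to_csv(self, path) -> None:
        write_results(self.rows, path)


def pretrain_subject(
    dataset: SubjectDataset,
    windowing: WindowingParams = WindowingParams(),
    config: TrainConfig | None = None,
    arch: PretextArchitecture = PretextArchitecture(),
    seed: int = 0,
) -> tuple[Sequential, dict, SubjectDataset]:
    """Normalize a subject and pre-train their forecaster on all pretext pairs.

    Returns the trained model, the training history, and the unit-scaled
    dataset (which downstream steps must reuse so train/test windows live on
    the same scale as the pre-training corpus).
    """
    scaled, _norm = normalize_recording(dataset.recording)
    ndataset = SubjectDataset(recording=scaled, reports=list(dataset.reports), source=dataset.source)
    pairs = make_pretext_pairs(scaled, windowing)
    if not pairs:
        raise ValidationError(
            f"recording of {len(scaled.samples)} samples is too short for one "
            f"pretext pair (needs {windowing.window_len + windowing.horizon})"
        )
    model = build_pretext_model(arch, seed=stable_seed("pretext-init", scaled.subject_id, seed))
    config = config or pretext_train_config()
    history = pretrain(model, pairs, replace(config, seed=stable_seed("pretext-fit", scaled.subject_id, seed)))
    return model, history, ndataset


def _question_pools(dataset, protocol, windowing):
    """Per-question (pool, test) window lists, drawn once before resampling."""
    subject = dataset.recording.subject_id
    question_ids = sorted({r.question_id for r in dataset.reports})
    pools = {}
    for q in question_ids:
        windows = make_labeled_windows(dataset, q, windowing, stride=protocol.labeled_stride)
        train, test = split_train_test(
            windows,
            protocol.test_fraction,
            mode=protocol.split_mode,
            seed=stable_seed("split", subject, q, protocol.split_seed),
        )
        if protocol.pool_size is not None and len(train) > protocol.pool_size:
            rng = np.random.default_rng(stable_seed("pool", subject, q, protocol.split_seed))
            keep = np.sort(rng.choice(len(train), protocol.pool_size, replace=False))
            train = [train[i] for i in keep]
        pools[q] = (train, test)
    return pools


def run_comparison(
    dataset: SubjectDataset,
    protocol: ProtocolConfig = ProtocolConfig(),
    train_cfg: TrainConfig | None = None,
    *,
    windowing: WindowingParams = WindowingParams(),
    pretext_cfg: TrainConfig | None = None,
    pretext_model: Sequential | None = None,
    downstream_arch: DownstreamArchitecture = DownstreamArchitecture(),
    budgets: tuple[int, ...] | None = None,
) -> ComparisonResult:
    """Run the paired SSL-vs-supervised comparison for one subject.

    If ``pretext_model`` is given, ``dataset`` must already be unit-scaled
    (as returned by :func:`pretrain_subject`); otherwise pre-training happens
    here. ``budgets`` defaults to the single ``protocol.label_budget``.
    """
    train_cfg = train_cfg or downstream_train_config()
    if pretext_model is None:
        pretext_model, _hist, dataset = pretrain_subject(
            dataset, windowing=windowing, config=pretext_cfg
        )
    subject = dataset.recording.subject_id
    budgets = tuple(budgets) if budgets is not None else (protocol.label_budget,)
    pools = _question_pools(dataset, protocol, windowing)

    # The frozen conv stack is identical in every SSL run (it is the pretext
    # model's), so conv features are computed once per distinct window and
    # reused across questions, budgets and resamples.
    probe = transfer_and_freeze(pretext_model, downstream_arch, seed=0)
    distinct: dict[int, object] = {}
    for pool, test in pools.values():
        for w in [*pool, *test]:
            distinct.setdefault(w.start_index, w)
    order = sorted(distinct)
    feat_x, _ = windows_to_arrays([distinct[s] for s in order])
    feats_all = extract_frozen_features(probe, feat_x)
    feat_of = {s: feats_all[i] for i, s in enumerate(order)}

    records = []
    for q, (pool, test) in pools.items():
        feats_pool = np.stack([feat_of[w.start_index] for w in pool])
        feats_test = np.stack([feat_of[w.start_index] for w in test])
        for budget in budgets:
            if budget > len(pool):
                raise ValidationError(
                    f"question {q}: budget {budget} exceeds the {len(pool)}-window "
                    f"pool (need >= {budget} train + {len(test)} test windows)"
                )
            # identical draws collapse to one training run per arm
            dedupe = budget == len(pool) and not protocol.sample_with_replacement
            cache = None
            for r in range(protocol.n_resamples):
                rng = np.random.default_rng(
                    stable_seed("draw", subject, q, budget, r, protocol.seeds[r])
                )
                idx = np.sort(
                    rng.choice(len(pool), budget, replace=protocol.sample_with_replacement)
                )
                draw_hash = stable_seed("hash", *idx.tolist())
                if dedupe and cache is not None:
                    ssl_rmse, sup_rmse = cache
                else:
                    sample = [pool[i] for i in idx]
                    ssl_model = transfer_and_freeze(
                        pretext_model,
                        downstream_arch,
                        seed=stable_seed("ssl-init", subject, q, budget, protocol.split_seed),
                    )
                    finetune(
                        ssl_model,
                        sample,
                        replace(train_cfg, seed=stable_seed("ssl-fit", subject, q, budget, protocol.split_seed)),
                        features=feats_pool[idx],
                    )
                    sup_model, _ = train_supervised(
                        downstream_arch,
                        sample,
                        replace(train_cfg, seed=stable_seed("sup-fit", subject, q, budget, protocol.split_seed)),
                        seed=stable_seed("sup-init", subject, q, budget, protocol.split_seed),
                    )
                    ssl_rmse = evaluate_regressor(ssl_model, test, features=feats_test)
                    sup_rmse = evaluate_regressor(sup_model, test)
                    if dedupe:
                        cache = (ssl_rmse, sup_rmse)
                for method, value in (("ssl", ssl_rmse), ("supervised", sup_rmse)):
                    records.append(
                        {
                            "subject_id": subject,
                            "question_id": q,
                            "method": method,
                            "budget": budget,
                            "resample": r,
                            "rmse": value,
                            "draw_hash": draw_hash,
                        }
                    )
    return ComparisonResult(rows=pd.DataFrame.from_records(records))


@dataclass
class LabelEfficiencyReport:
    """Budget-sweep outcome for one subject."""

    result: ComparisonResult
    curve: pd.DataFrame  # per method × budget: mean_rmse, sd_rmse
    crossing_budget: int | None
    crossing_fraction_pct: float | None
    supervised_full_rmse: float


def label_efficiency_curve(
    dataset: SubjectDataset,
    protocol: ProtocolConfig = ProtocolConfig(),
    train_cfg: TrainConfig | None = None,
    **kwargs,
) -> LabelEfficiencyReport:
    """Sweep label budgets and locate the SSL/supervised crossing point.

    Pre-trains once, runs the paired comparison at every budget in
    ``protocol.budget_sweep``, and reports the smallest budget at which the
    SSL arm's mean test RMSE (across questions and resamples) is at or below
    the supervised arm's mean RMSE at the largest budget — the label cost of
    matching a fully labelled supervised model. The crossing fraction is that
    budget as a percentage of the largest budget.
    """
    pretext_model = kwargs.pop("pretext_model", None)
    windowing = kwargs.get("windowing", WindowingParams())
    if pretext_model is None:
        pretext_model, _h, dataset = pretrain_subject(
            dataset, windowing=windowing, config=kwargs.pop("pretext_cfg", None)
        )
    result = run_comparison(
        dataset,
        protocol,
        train_cfg,
        pretext_model=pretext_model,
        budgets=protocol.budget_sweep,
        **kwargs,
    )
    curve = (
        result.rows.groupby(["method", "budget"])["rmse"]
        .agg(mean_rmse="mean", sd_rmse="std")
        .reset_index()
    )
    top_budget = max(protocol.budget_sweep)
    sup_full = float(
        curve.query("method == 'supervised' and budget == @top_budget")["mean_rmse"].iloc[0]
    )
    ssl_curve = curve.query("method == 'ssl'").sort_values("budget")
    crossing = None
    for _, row in ssl_curve.iterrows():
        if row["mean_rmse"] <= sup_full:
            crossing = int(row["budget"])
            break
    return LabelEfficiencyReport(
        result=result,
        curve=curve,
        crossing_budget=crossing,
        crossing_fraction_pct=(100.0 * crossing / top_budget) if crossing else None,
        supervised_full_rmse=sup_full,
    )


@dataclass
class StudyResult:
    """Multi-subject label-efficiency study outcome."""

    reports: dict  # subject_id -> LabelEfficiencyReport
    rows: pd.DataFrame
    crossing_fractions_pct: list[float]
    median_crossing_pct: float
    stability_fraction: float  # fraction of cells with sd(ssl) <= sd(supervised)
    pretext_val_rmse: dict  # subject_id -> final validation forecast RMSE


def default_study_protocol(seed: int = 0) -> ProtocolConfig:
    """The multi-subject benchmark protocol at its published scale.

    Budgets {10, 20, 30, 50, 75, 100} from a 100-window pool, five paired
    resamples, a 20% held-out test split; labelled windows are tiled at a
    6000-sample stride so a ~20-minute recording yields a pool of 100.
    """
    return ProtocolConfig(labeled_stride=6000, split_seed=seed)


def label_efficiency_study(
    subject_seeds=(0, 1, 2),
    seed: int = 0,
    protocol: ProtocolConfig | None = None,
    windowing: WindowingParams = WindowingParams(),
    pretext_cfg: TrainConfig | None = None,
    train_cfg: TrainConfig | None = None,
    log=None,
) -> StudyResult:
    """Run the full SSL-vs-supervised label-efficiency benchmark.

    Simulates one subject per entry of ``subject_seeds`` with the simulator
    defaults, pre-trains each subject's forecaster on all their pretext
    pairs, sweeps the label budgets with paired resamples, and aggregates:

    * the median (over subjects) smallest budget — as a percentage of the
      full pool — at which the SSL arm matches the supervised arm trained on
      the whole pool, and
    * the fraction of (subject, question, budget) cells in which the SSL
      arm's RMSE spread across resamples is at most the supervised arm's.

    ``seed`` perturbs every stochastic component (splits, draws, inits).
    """
    from .data_io import dataset_from_recording
    from .simulate import default_sim_config, simulate_subject

    protocol = protocol or default_study_protocol(seed)
    pretext_cfg = pretext_cfg or pretext_train_config(max_epochs=2, patience=0)
    train_cfg = train_cfg or downstream_train_config()
    reports: dict = {}
    pretext_val: dict = {}
    all_rows = []
    for s_seed in subject_seeds:
        recording = simulate_subject(default_sim_config(s_seed))
        dataset = dataset_from_recording(recording)
        model, hist, scaled = pretrain_subject(
            dataset, windowing=windowing, config=pretext_cfg, seed=seed
        )
        pretext_val[recording.subject_id] = hist["val_rmse"][-1]
        if log:
            log("pretrained %s: forecast val RMSE %.4f", recording.subject_id, hist["val_rmse"][-1])
        report = label_efficiency_curve(
            scaled,
            protocol,
            replace(train_cfg, seed=stable_seed(train_cfg.seed, seed)),
            windowing=windowing,
            pretext_model=model,
        )
        reports[recording.subject_id] = report
        all_rows.append(report.result.rows)
        if log:
            log(
                "subject %s: crossing budget %s (supervised full-pool RMSE %.4f)",
                recording.subject_id,
                report.crossing_budget,
                report.supervised_full_rmse,
            )

    rows = pd.concat(all_rows, ignore_index=True)
    top = max(protocol.budget_sweep)
    fractions = [
        r.crossing_fraction_pct if r.crossing_fraction_pct is not None else 100.0
        for r in reports.values()
    ]
    # stability: spread across resamples, on budgets where draws vary
    sub = rows[rows["budget"] < top]
    sds = (
        sub.groupby(["subject_id", "question_id", "budget", "method"])["rmse"]
        .std()
        .unstack("method")
    )
    stability = float((sds["ssl"] <= sds["supervised"]).mean())
    return StudyResult(
        reports=reports,
        rows=rows,
        crossing_fractions_pct=fractions,
        median_crossing_pct=float(np.median(fractions)),
        stability_fraction=stability,
        pretext_val_rmse=pretext_val,
    )


def summarize(result: ComparisonResult, out_dir=None) -> dict:
    """Aggregate a comparison table: per-cell mean/sd, and the SSL win rate.

    The win rate is the fraction of paired cells in which the SSL arm's RMSE
    is strictly below the supervised arm's; ties count as non-wins. With
    ``out_dir`` set, writes ``results.csv``, ``summary.csv`` and
    ``win_rate.csv``.
    """
    rows = result.rows
    if rows.empty:
        raise ValidationError("cannot summarize an empty comparison result")
    keys = ["subject_id", "question_id", "budget", "resample"]
    wide = rows.pivot_table(index=keys, columns="method", values="rmse").reset_index()
    if not {"ssl", "supervised"}.issubset(wide.columns):
        raise ValidationError("result must contain both methods for every cell")
    wide["ssl_win"] = wide["ssl"] < wide["supervised"]
    win_rate = float(wide["ssl_win"].mean())
    per_question = (
        wide.groupby("question_id")
        .agg(
            ssl_mean=("ssl", "mean"),
            ssl_sd=("ssl", "std"),
            supervised_mean=("supervised", "mean"),
            supervised_sd=("supervised", "std"),
            win_rate=("ssl_win", "mean"),
        )
        .reset_index()
    )
    out = {
        "summary": result.summary(),
        "per_question": per_question,
        "win_rate": win_rate,
        "n_cells": int(len(wide)),
    }
    if out_dir is not None:
        from pathlib import Path

        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        result.to_csv(out_path / "results.csv")
        out["summary"].to_csv(out_path / "summary.csv", index=False)
        per_question.assign(overall_win_rate=win_rate).to_csv(
            out_path / "win_rate.csv", index=False
        )
    return out
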