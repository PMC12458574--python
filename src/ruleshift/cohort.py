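"""Synthetic participants and two-group cohorts for the rule-shifting task.

The generative agent is deliberately minimal: it is the simplest model
able to produce the three phenomena the analysis pipeline is built to
detect — matched choice accuracy across groups, a stable group gap in
confidence level (metacognitive bias), and a group difference in how
strongly trial-wise confidence couples to Bayes-optimal Choice Certainty
(evidence tracking).

Choices: softmax over the per-stimulus Choice Certainty of the ideal
observer's prior belief, with inverse temperature ``inv_temp`` and a
``lapse`` probability of a uniformly random choice. Confidence:

    conf_t = clip( b + w_cc * z(CC_t) + w_gc * z(GC_t)
                     + w_fb * (r_{t-1} - 1/2) + eps_t , 1, 100 )

with CC/GC the pre-feedback observer traces standardised within
participant, r_{t-1} the previous trial's outcome within level (1/2,
i.e. neutral, on a level's first trial), and eps_t Gaussian. The explicit
feedback-valence term exists because normative Choice Certainty is
mean-reverting after correct trials under per-trial layout
re-randomisation: certainty coupling alone cannot raise or lower the
average post-correct confidence change, which is a group phenomenon the
cohorts must be able to express. RTs are lognormal and play no role in
the agent's behaviour (they exist to exercise the RT outlier filter).

Default group presets give both groups identical choice parameters
(accuracy matched) while the patient group's confidence intercept is
lowered by ``delta_b`` slider units, its CC weight raised by ``delta_w``
and its feedback-valence weight raised by ``delta_fb``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import LevelSpec, TrialRecord, make_default_levels, sample_shift_schedule, sample_trial_layout
from .observer import PROB_FLOOR, run_observer

__all__ = [
    "AgentParams",
    "GroupSpec",
    "CohortDataset",
    "default_group_specs",
    "simulate_participant",
    "simulate_cohort",
    "recovery_experiment",
]

_RESET_TOL = 1e-12


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic participant.

    ``inv_temp`` acts on Choice Certainty expressed as a probability
    (CC/100); ``b``, ``w_cc``, ``w_gc`` and ``conf_noise_sd`` are in
    confidence-slider units; ``rt_mu``/``rt_sigma`` parameterise a
    lognormal RT in seconds.
    """

    inv_temp: float = 5.0
    lapse: float = 0.05
    conf_intercept: float = 70.0
    w_cc: float = 6.0
    w_gc: float = 1.5
    w_fb: float = 1.5
    conf_noise_sd: float = 10.0
    rt_mu: float = 0.3
    rt_sigma: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")
        if self.conf_noise_sd <= 0:
            raise ValueError("conf_noise_sd must be positive")
        if self.inv_temp < 0:
            raise ValueError("inv_temp must be nonnegative")


@dataclass(frozen=True)
class GroupSpec:
    """Population-level description of one group of synthetic participants.

    ``param_means``/``param_sds`` give, per AgentParams field, the mean and
    between-participant SD of that parameter. Gender is coded as in the
    demographics table: 1 = female, 2 = male, 0 = non-binary/other.
    """

    label: str
    n: int
    param_means: dict
    param_sds: dict
    age_mean: float = 31.0
    age_sd: float = 11.0
    gender_probs: tuple[float, float, float] = (0.48, 0.48, 0.04)  # (1, 2, 0)
    iq_mean: float = 30.0
    iq_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group needs n >= 2")


@dataclass
class CohortDataset:
    """Trial logs, demographics, ground-truth parameters, raw records."""

    trials: pd.DataFrame
    demographics: pd.DataFrame
    truth: pd.DataFrame
    records: Optional[dict] = None  # participant_id -> list[TrialRecord]


_DEFAULT_MEANS = dict(inv_temp=5.0, lapse=0.05, conf_intercept=70.0, w_cc=6.0,
                      w_gc=1.5, w_fb=1.5, conf_noise_sd=10.0, rt_mu=0.3,
                      rt_sigma=0.4)
_DEFAULT_SDS = dict(inv_temp=1.0, lapse=0.03, conf_intercept=10.0, w_cc=1.5,
                    w_gc=1.0, w_fb=1.0, conf_noise_sd=2.0, rt_mu=0.15,
                    rt_sigma=0.05)


def default_group_specs(delta_b: float = 12.0, delta_w: float = 3.0,
                        n_per_group: int = 29,
                        delta_fb: float = 2.0) -> tuple[GroupSpec, GroupSpec]:
    """Preset (patient, control) specs.

    The patient group's mean confidence intercept sits ``delta_b`` slider
    units below the control group's, its mean CC weight ``delta_w`` units
    above, and its feedback-valence weight ``delta_fb`` units above; all
    choice parameters are identical, so group accuracy is matched by
    construction. Setting every delta to 0 gives the null preset.
    """
    control = GroupSpec("control", n_per_group, dict(_DEFAULT_MEANS), dict(_DEFAULT_SDS))
    means = dict(_DEFAULT_MEANS)
    means["conf_intercept"] -= delta_b
    means["w_cc"] += delta_w
    means["w_fb"] += delta_fb
    ocd = GroupSpec("OCD", n_per_group, means, dict(_DEFAULT_SDS))
    return ocd, control


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_participant(
    levels: Sequence[LevelSpec],
    params: AgentParams,
    seed,
    participant_id: str = "sim",
) -> list[TrialRecord]:
    """Simulate one participant's full task run.

    Returns TrialRecords with choices, outcomes, confidence and RT filled
    in. The observer computations used for action selection are internal;
    downstream analyses recompute traces from the log via ``run_observer``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_records: list[TrialRecord] = []
    cc_pre_all: list[float] = []
    gc_pre_all: list[float] = []
    prev_outcome_all: list[float] = []  # 0.5 = neutral (level start)

    for level in levels:
        prev_outcome = 0.5
        schedule = sample_shift_schedule(level, rng)
        rules = schedule.rules_by_trial(level.n_trials)
        shift_at = {ev.trial_index: ev.shift_type for ev in schedule.events}
        features = level.features
        n_feat = len(features)
        feat_index = {f: k for k, f in enumerate(features)}
        log2n = np.log2(n_feat)
        probs = np.full(n_feat, 1.0 / n_feat)

        for t in range(level.n_trials):
            display = sample_trial_layout(level, rng)
            stim_idx = [np.array([feat_index[f] for f in s]) for s in display.stimuli]
            cc_stim = np.array([probs[ix].sum() for ix in stim_idx])

            if params.inv_temp == 0.0 or rng.random() < params.lapse:
                choice = int(rng.integers(display.n_stimuli))
            else:
                logits = params.inv_temp * cc_stim
                logits -= logits.max()
                p = np.exp(logits)
                p /= p.sum()
                choice = int(rng.choice(display.n_stimuli, p=p))

            outcome = int(rules[t].rewarded_feature in display.stimuli[choice])

            pos = probs[probs > 0]
            entropy = -(pos * np.log2(pos)).sum()
            gc_pre_all.append(100.0 * (log2n - entropy) / log2n)
            cc_pre_all.append(100.0 * cc_stim[choice])
            prev_outcome_all.append(prev_outcome)
            prev_outcome = float(outcome)

            # Bayes update with reset on contradiction
            chosen_mask = np.zeros(n_feat, dtype=bool)
            chosen_mask[stim_idx[choice]] = True
            n_c = chosen_mask.sum()
            n_u = n_feat - n_c
            if outcome == 1:
                lik = np.where(chosen_mask, 1.0 / n_c, 0.0)
            else:
                lik = np.where(chosen_mask, 0.0, 1.0 / n_u)
            prior = np.where(probs < PROB_FLOOR, 0.0, probs)
            unnorm = lik * prior
            z = unnorm.sum()
            probs = np.full(n_feat, 1.0 / n_feat) if z < _RESET_TOL else unnorm / z

            all_records.append(
                TrialRecord(
                    participant_id=participant_id,
                    level_id=level.level_id,
                    block=level.block_of(t),
                    trial_index=t,
                    display=display,
                    rule=rules[t],
                    is_shift_trial=t in shift_at,
                    shift_type=shift_at.get(t, "none"),
                    choice=choice,
                    outcome=outcome,
                    slider_start=int(rng.integers(1, 101)),
                )
            )

    cc = np.asarray(cc_pre_all)
    gc = np.asarray(gc_pre_all)
    fb = np.asarray(prev_outcome_all) - 0.5
    conf = (
        params.conf_intercept
        + params.w_cc * _zscore(cc)
        + params.w_gc * _zscore(gc)
        + params.w_fb * fb
        + rng.normal(0.0, params.conf_noise_sd, cc.size)
    )
    conf = np.clip(np.rint(conf), 1, 100)
    rt = rng.lognormal(params.rt_mu, params.rt_sigma, cc.size)
    for rec, c, r in zip(all_records, conf, rt):
        rec.confidence = float(c)
        rec.rt = float(r)
    return all_records


def _sample_params(spec: GroupSpec, rng: np.random.Generator) -> AgentParams:
    kw = {}
    for name, mu in spec.param_means.items():
        sd = spec.param_sds.get(name, 0.0)
        kw[name] = rng.normal(mu, sd) if sd > 0 else mu
    kw["lapse"] = float(np.clip(kw.get("lapse", 0.0), 0.0, 1.0))
    kw["inv_temp"] = max(0.0, kw.get("inv_temp", 0.0))
    kw["conf_noise_sd"] = max(0.5, kw.get("conf_noise_sd", 1.0))
    kw["rt_sigma"] = max(0.05, kw.get("rt_sigma", 0.1))
    return AgentParams(**kw)


def simulate_cohort(
    ocd: GroupSpec,
    control: GroupSpec,
    seed,
    levels: Optional[Sequence[LevelSpec]] = None,
) -> CohortDataset:
    """Simulate a full two-group cohort (trial logs + demographics + truth)."""
    from .io import records_to_frame

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if levels is None:
        levels = make_default_levels()

    frames, demo_rows, truth_rows = [], [], {}
    records: dict[str, list[TrialRecord]] = {}
    counter = 0
    for spec in (ocd, control):
        for i in range(spec.n):
            pid = f"{spec.label.lower()}_{i:03d}"
            counter += 1
            params = _sample_params(spec, rng)
            recs = simulate_participant(levels, params, rng, participant_id=pid)
            records[pid] = recs
            frames.append(records_to_frame(recs))
            age = int(np.clip(np.rint(rng.normal(spec.age_mean, spec.age_sd)), 18, 55))
            gender = int(rng.choice([1, 2, 0], p=spec.gender_probs))
            iq = float(np.clip(rng.normal(spec.iq_mean, spec.iq_sd), 2.0, 60.0))
            demo_rows.append((pid, spec.label, age, gender, iq))
            truth_rows[pid] = params

    trials = pd.concat(frames, ignore_index=True)
    demographics = pd.DataFrame(
        demo_rows, columns=["participant_id", "group", "age", "gender", "iq"]
    )
    truth = pd.DataFrame(
        [{"participant_id": pid, **vars(p)} for pid, p in truth_rows.items()]
    )
    return CohortDataset(trials, demographics, truth, records)


def cohort_traces(cohort: CohortDataset) -> pd.DataFrame:
    """Ideal-observer traces for every participant in a cohort."""
    if cohort.records is None:
        raise ValueError("cohort has no raw records; re-read trial logs first")
    return pd.concat(
        [run_observer(recs) for recs in cohort.records.values()], ignore_index=True
    )


def recovery_experiment(
    delta_b: float,
    delta_w: float,
    n_per_group: int,
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    apply_exclusions_first: bool = True,
) -> dict:
    """Simulate-fit-recover loop for the two group-level confidence effects.

    For each replicate: simulate a cohort under the given presets, run the
    observer, apply the task exclusion rules, fit the joint normative
    confidence model, and record the estimated group main effect (the
    confidence-intercept gap, target value ``-delta_b``) and the CC x
    group interaction (target ``+delta_w``).

    Returns a dict with the per-replicate table and summary statistics
    (bias, RMSE, sign-recovery rate = sign correct and p < alpha). The
    feedback-valence weight is group-equal here (delta_fb = 0), so the
    recovery targets are exactly the two stated effects and the null
    preset (delta_b = delta_w = 0) is fully null.
    """
    from .pipeline import apply_exclusions, fit_normative_model

    root = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        ocd, control = default_group_specs(delta_b, delta_w, n_per_group,
                                           delta_fb=0.0)
        cohort = simulate_cohort(ocd, control, rng)
        if apply_exclusions_first:
            cohort, _ = apply_exclusions(cohort)
        traces = cohort_traces(cohort)
        res = fit_normative_model(cohort, traces, spec="joint")
        coefs = res.coef.set_index("term")
        rows.append(
            dict(
                rep=rep,
                group_beta=coefs.loc["group", "estimate"],
                group_p=coefs.loc["group", "p"],
                ccxgroup_beta=coefs.loc["zcc:group", "estimate"],
                ccxgroup_p=coefs.loc["zcc:group", "p"],
                converged=res.converged,
            )
        )
    table = pd.DataFrame(rows)

    def _summary(est, p, truth):
        sign_ok = (np.sign(est) == np.sign(truth)) if truth != 0 else np.zeros(len(est), bool)
        return dict(
            mean_estimate=float(est.mean()),
            bias=float(est.mean() - truth),
            rmse=float(np.sqrt(((est - truth) ** 2).mean())),
            sign_recovery_rate=float((sign_ok & (p < alpha)).mean()),
            rejection_rate=float((p < alpha).mean()),
        )

    return dict(
        table=table,
        group_effect=_summary(table.group_beta, table.group_p, -delta_b),
        cc_interaction=_summary(table.ccxgroup_beta, table.ccxgroup_p, delta_w),
    )
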