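"""Config-driven orchestration of the full analysis on one session.

Stages: bin spikes at 250 ms -> (optional) two-step FA dimensionality
selection -> GPFA -> sticky Gaussian HMM (restarts; fixed or
cross-validated K) -> Viterbi segmentation and state posteriors ->
correspondence statistics against the behavioral segmentation (MI with
permutation nulls, cell-wise conditional probabilities, role separation
when observing trials exist, per-behavior state timecourses) -> decoding
sanity check. Every random draw traces to the top-level seed; the run
writes a machine-readable ``report.json`` plus segmentation and
state-posterior tables.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import data, decoding, gpfa, hmm, matching, preprocessing, stats, synthetic
from .data import Segmentation, SpikeSession

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def default_config() -> Dict[str, Any]:
    """Pipeline defaults: 250 ms bins, sticky HMM (alpha=1, kappa=100,
    40 restarts), K=11 for play sessions, 10,000-draw nulls."""
    return {
        "seed": 0,
        "session_dir": None,     # path to an on-disk session, or use synthesis
        "synthesis": None,       # dict of SyntheticConfig overrides
        "analysis": {
            "bin_width_s": 0.25,
            "latent_dim": None,          # fixed d; None -> two-step selection
            "candidate_dims": None,      # default 1..min(8, n_neurons - 1)
            "fa_folds": 5,
            "gpfa_max_iter": 50,
            "K": 11,                     # 18 is the observing-session default
            "candidate_Ks": None,        # list -> 10-fold CV selection
            "cv_folds": 10,
            "hmm": {"alpha": 1.0, "kappa": 100.0, "n_restarts": 40,
                    "tol": 1e-7, "max_iter": 200},
            "n_null": 10_000,
            "decode": True,
            "decode_folds": 10,
            "timecourses": True,
            "timecourse_pad_s": 1.0,
        },
    }


def load_config(path: str | Path) -> Dict[str, Any]:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    _deep_update(cfg, user)
    return cfg


def _deep_update(base: Dict, extra: Mapping) -> None:
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def make_synthetic_config(overrides: Optional[Mapping] = None) -> synthetic.SyntheticConfig:
    cfg = synthetic.SyntheticConfig()
    for k, v in (overrides or {}).items():
        if not hasattr(cfg, k):
            raise synthetic.ConfigurationError(f"unknown synthesis key {k!r}")
        setattr(cfg, k, v)
    return cfg


def obtain_session(config: Mapping, seed: int):
    """Load the configured session directory or synthesize one."""
    if config.get("session_dir"):
        return data.read_session(config["session_dir"]), None
    syn = make_synthetic_config(config.get("synthesis") or {})
    return synthetic.generate_session(syn, seed)


def fit_session(
    session: SpikeSession, analysis: Mapping, seed: int
) -> Dict[str, Any]:
    """Binning, dimensionality selection, GPFA and the sticky HMM."""
    w = analysis["bin_width_s"]
    binned = {}
    for t in session.trials:
        b = preprocessing.bin_spikes(session, t.trial_id, w)
        if b.n_bins >= 2:
            binned[t.trial_id] = b
    stacked = np.concatenate(
        [b.counts.T for b in binned.values()], axis=0
    ).astype(float)

    d = analysis.get("latent_dim")
    fa_scores = None
    if d is None:
        cands = analysis.get("candidate_dims") or list(
            range(1, min(8, session.n_neurons - 1) + 1)
        )
        d, fa_scores = gpfa.select_dimensionality(
            stacked, cands, folds=analysis["fa_folds"], seed=seed
        )
        logger.info("selected latent dimensionality d=%d", d)

    model_gpfa, latents = gpfa.fit_gpfa(
        binned, d, seed=seed, max_iter=analysis["gpfa_max_iter"]
    )

    hmm_cfg = hmm.HMMFitConfig(base_seed=seed, **analysis["hmm"])
    K = analysis.get("K")
    cv_scores = None
    if analysis.get("candidate_Ks"):
        K, cv_scores = hmm.select_num_states(
            latents, analysis["candidate_Ks"],
            folds=min(analysis["cv_folds"], len(latents)), config=hmm_cfg,
        )
        logger.info("cross-validation chose K=%d", K)
    model_hmm, diagnostics = hmm.fit_sticky_hmm(latents, K, hmm_cfg)
    viterbi = hmm.decode_segmentation(model_hmm, latents, method="viterbi")
    gammas = hmm.state_posteriors(model_hmm, latents)

    return {
        "binned": binned,
        "latent_dim": d,
        "fa_cv_scores": fa_scores,
        "gpfa_model": model_gpfa,
        "latents": latents,
        "K": K,
        "K_cv_scores": cv_scores,
        "hmm_model": model_hmm,
        "hmm_diagnostics": diagnostics,
        "segmentation": Segmentation(bin_width_s=w, labels=viterbi),
        "gammas": gammas,
    }


def compute_statistics(
    session: SpikeSession, fit: Mapping, analysis: Mapping, seed: int
) -> Dict[str, Any]:
    w = analysis["bin_width_s"]
    hmm_seg: Segmentation = fit["segmentation"]
    beh_seg = stats.behavioral_segmentation(session, w)
    beh_seg.labels = {tid: beh_seg.labels[tid][: len(hmm_seg.labels[tid])]
                      for tid in hmm_seg.trial_ids()}
    n_null = analysis["n_null"]

    out: Dict[str, Any] = {"behavior_segmentation": beh_seg}
    mi = stats.mi_significance(
        hmm_seg, beh_seg, null="segment_shuffle", n_null=n_null, seed=seed + 1
    )
    out["mi_segment_shuffle"] = _mi_summary(mi)
    out["mi_cyclic_rotation"] = _mi_summary(
        stats.mi_significance(hmm_seg, beh_seg, null="cyclic_rotation")
    )
    cond = stats.conditional_significance(
        hmm_seg, beh_seg, n_null=n_null, seed=seed + 1
    )
    out["conditional"] = cond

    roles = {t.trial_id: t.role for t in session.trials}
    if "observing" in set(roles.values()) and len(set(roles.values())) > 1:
        out["role_separation"] = stats.role_state_separation(
            hmm_seg, roles, n_states=fit["K"], n_null=n_null, seed=seed + 2
        )

    if analysis.get("timecourses"):
        behaviors = sorted(
            {lab for t in session.trials for lab, _, _ in t.behavior_intervals}
        )
        tcs = {}
        for b in behaviors:
            tc = stats.state_behavior_timecourse(
                fit["gammas"], session, b, bin_width_s=w,
                pad_s=analysis["timecourse_pad_s"],
            )
            if tc is not None:
                tcs[b] = tc
        out["behavior_timecourses"] = tcs

    if analysis.get("decode"):
        beh_labels = {tid: beh_seg.labels[tid] for tid in hmm_seg.trial_ids()}
        folds = min(analysis["decode_folds"], len(beh_labels))
        out["decoding"] = decoding.decode_vs_baselines(
            fit["latents"], beh_labels, folds=folds, seed=seed + 3
        )
    return out


def _mi_summary(mi: Mapping) -> Dict[str, Any]:
    null = np.asarray(mi["null_mi"])
    return {
        "observed_mi": mi["observed_mi"],
        "p": mi["p"],
        "p_value": mi["p_value"],
        "below_resolution": mi["below_resolution"],
        "n_null": mi["n_null"],
        "null_mean": float(null.mean()),
        "null_std": float(null.std()),
        "null_max": float(null.max()),
        "null_kind": mi["null_kind"],
    }


def run_pipeline(
    config: Mapping | str | Path, out_dir: str | Path, seed: Optional[int] = None
) -> Dict[str, Any]:
    """Execute the full analysis and write artifacts to ``out_dir``."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    config = copy.deepcopy(dict(config))
    if seed is not None:
        config["seed"] = seed
    seed = int(config.get("seed", 0))
    analysis = config["analysis"]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    session, truth = obtain_session(config, seed)
    logger.info(
        "session %s: %d neurons, %d trials", session.session_id,
        session.n_neurons, len(session.trials),
    )
    fit = fit_session(session, analysis, seed)
    statistics = compute_statistics(session, fit, analysis, seed)

    report: Dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": seed,
        "session_id": session.session_id,
        "n_neurons": session.n_neurons,
        "n_trials": len(session.trials),
        "latent_dim": fit["latent_dim"],
        "fa_cv_scores": fit["fa_cv_scores"],
        "K": fit["K"],
        "K_cv_scores": fit["K_cv_scores"],
        "gpfa_taus_s": fit["gpfa_model"].taus,
        "hmm_restart_objectives": fit["hmm_diagnostics"]["restart_objectives"],
        "hmm_best_restart": fit["hmm_diagnostics"]["best_restart"],
        "mi_segment_shuffle": statistics["mi_segment_shuffle"],
        "mi_cyclic_rotation": statistics["mi_cyclic_rotation"],
        "conditional": _conditional_report(statistics["conditional"]),
        "runtime_s": None,
        "stage_seeds": {
            "gpfa_and_hmm": seed, "mi_null": seed + 1,
            "role_null": seed + 2, "decoding": seed + 3,
        },
    }
    if "role_separation" in statistics:
        rs = statistics["role_separation"]
        report["role_separation"] = {
            "p_observing_given_state": rs["p_observing_given_state"],
            "mixing_fraction": rs["mixing_fraction"],
            "role_mi": rs["role_mi"],
            "p": rs["p"],
            "below_resolution": rs["below_resolution"],
        }
    if "decoding" in statistics:
        dec = statistics["decoding"]
        report["decoding"] = {
            k: dec[k]
            for k in ("accuracy_classifier", "accuracy_stratified",
                      "accuracy_most_frequent", "p_value")
        }
    report["runtime_s"] = round(time.time() - t0, 2)

    segs = {
        "hmm": fit["segmentation"],
        "behavior": statistics["behavior_segmentation"],
    }
    data.write_results(segs, report, out_dir)
    _write_gammas(fit["gammas"], out_dir / "state_posteriors.csv")
    _write_models(fit, out_dir / "model.json")
    return {
        "session": session, "truth": truth, "fit": fit,
        "statistics": statistics, "report": report,
    }


def _conditional_report(cond: Mapping) -> Dict[str, Any]:
    return {
        "states": cond["states"],
        "behaviors": cond["behaviors"],
        "p_beh_given_state": cond["observed"].p_beh_given_state,
        "p_state_given_beh": cond["observed"].p_state_given_beh,
        "stars_beh_given_state": cond["stars_beh_given_state"],
        "stars_state_given_beh": cond["stars_state_given_beh"],
        "n_significant": int(cond["stars_beh_given_state"].sum()
                             + cond["stars_state_given_beh"].sum()),
    }


def _write_gammas(gammas: Mapping[int, np.ndarray], path: Path) -> None:
    rows = []
    for tid, g in gammas.items():
        for t in range(g.shape[0]):
            for k in range(g.shape[1]):
                rows.append((tid, t, k, g[t, k]))
    pd.DataFrame(
        rows, columns=["trial_id", "bin_index", "state", "probability"]
    ).to_csv(path, index=False)


def _write_models(fit: Mapping, path: Path) -> None:
    """Fitted GPFA and HMM parameters as a JSON artifact."""
    g = fit["gpfa_model"]
    h = fit["hmm_model"]
    payload = {
        "gpfa": {
            "C": g.C, "d_vec": g.d_vec, "R": g.R, "taus_s": g.taus,
            "sigma_n2": g.sigma_n2, "bin_width_s": g.bin_width_s,
        },
        "hmm": {
            "pi0": h.pi0, "A": h.A, "means": h.means, "covs": h.covs,
        },
    }
    with open(path, "w") as fh:
        json.dump(data._jsonable(payload), fh)


def read_gammas(path: str | Path) -> Dict[int, np.ndarray]:
    df = pd.read_csv(path)
    out = {}
    for tid, grp in df.groupby("trial_id"):
        T = grp["bin_index"].max() + 1
        K = grp["state"].max() + 1
        g = np.zeros((T, K))
        g[grp["bin_index"], grp["state"]] = grp["probability"]
        out[int(tid)] = g
    return out


def match_sessions(
    run_dirs: Mapping[str, str | Path],
    session_dirs: Mapping[str, str | Path],
    bin_width_s: float = 0.25,
    roles=("hide", "seek"),
) -> Dict[str, Any]:
    """Cross-session state matching from saved pipeline outputs.

    ``run_dirs`` maps session ids to pipeline output directories (for
    ``state_posteriors.csv``); ``session_dirs`` to the session data.
    """
    sessions = {sid: data.read_session(p) for sid, p in session_dirs.items()}
    gammas = {sid: read_gammas(Path(p) / "state_posteriors.csv")
              for sid, p in run_dirs.items()}
    anchors = {
        role: matching.global_anchors(list(sessions.values()), role, bin_width_s)
        for role in roles
        if any(s.trials_of_role(role) for s in sessions.values())
    }
    tcs = {
        sid: {
            role: tc
            for role in anchors
            if (tc := matching.state_probability_timecourse(
                gammas[sid], sessions[sid], role, anchors[role]
            )) is not None
        }
        for sid in sessions
    }
    ref, matches = matching.select_reference(tcs, roles=list(anchors.keys()))
    return {"reference": ref, "matches": matches, "timecourses": tcs,
            "anchors": anchors}
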