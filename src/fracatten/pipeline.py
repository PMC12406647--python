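"""End-to-end orchestration: IKIs → DFA → surrogate test; epochs →
component measures → contrasts; α joined with component attenuation →
mixed model → Bayes factor. One structured, self-describing report.

Desk-scale defaults (8 participants, 64 epochs per cell, 100 shuffles)
keep a full run fast; ``paper_scale=True`` switches to the study's sizes
(21 participants, 525 keypresses/epochs per block, 500 shuffles).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .containers import IKISeries, SOA_LEVELS
from .erp import (
    N1_POOL,
    P2_POOL,
    collapsed_localizer,
    mean_amplitude,
    motor_correct,
    process_epochs,
)
from .fractal import dfa, generate_window_sizes
from .stats import (
    adjust_contrasts,
    bic_bayes_factor,
    fit_random_intercept_lmm,
    paired_contrast,
    rm_anova_2x3,
)
from .surrogate import surrogate_anova_test
from .synthetic_data import default_erp_spec, simulate_epochs, simulate_study_ikis

SCHEMA_VERSION = "1"

REPORT_REQUIRED_KEYS = {
    "schema_version", "config", "provenance", "behavior", "erp", "linking",
}


@dataclass
class RunConfig:
    """Configuration for a full synthetic run. Defaults are the study's
    protocol constants; any override is echoed verbatim in the report."""

    seed: int = 0
    n_participants: int = 8
    soa_levels: tuple[float, ...] = SOA_LEVELS
    keypresses_per_block: int = 525
    discard_ikis: int = 12
    n_epochs_per_cell: int = 64
    drop_initial_epochs: int = 13
    rejection_threshold_uv: float = 200.0
    n_shuffles: int = 100
    dfa_base: int = 4
    dfa_factor: float = 1.2
    component_width_ms: float = 30.0
    n1_pool: tuple[str, ...] = tuple(N1_POOL)
    p2_pool: tuple[str, ...] = tuple(P2_POOL)
    n1_search_ms: tuple[float, float] = (50.0, 150.0)
    p2_search_ms: tuple[float, float] = (120.0, 220.0)
    noise_rms_uv: float = 10.0
    fs: float = 1024.0

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "RunConfig":
        return cls(seed=seed, n_participants=21, n_epochs_per_cell=525,
                   n_shuffles=500)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _trim_series(s: IKISeries, discard: int) -> IKISeries:
    return IKISeries(
        participant_id=s.participant_id, production=s.production, soa=s.soa,
        intervals=s.intervals[discard:],
        meta={**s.meta, "discarded_initial": discard},
    )


def run_behavior(config: RunConfig, rng_seed: int) -> dict:
    """Behavioral stage: simulate, trim transients, DFA, ANOVA, surrogate."""
    n_ikis = config.keypresses_per_block - 1
    raw = simulate_study_ikis(config.n_participants, n=n_ikis, seed=rng_seed)
    series = [_trim_series(s, config.discard_ikis) for s in raw]

    ladder = generate_window_sizes(n_ikis - config.discard_ikis,
                                   base=config.dfa_base,
                                   factor=config.dfa_factor)
    rows = []
    for s in series:
        r = dfa(s, ladder)
        rows.append({
            "participant": s.participant_id, "production": s.production,
            "soa": s.soa, "alpha": r.alpha, "r_squared": r.r_squared,
            "classification": r.classification,
            "mean_iki_s": float(s.intervals.mean()),
            "sd_iki_s": float(s.intervals.std(ddof=1)),
            "group_target_alpha": s.meta.get("group_target_alpha"),
        })
    alpha_df = pd.DataFrame(rows)

    anova = rm_anova_2x3(alpha_df.rename(columns={"alpha": "value"}))
    surr = surrogate_anova_test(series, n_shuffles=config.n_shuffles,
                                seed=rng_seed + 1, soa_levels=config.soa_levels,
                                ladder_base=config.dfa_base,
                                ladder_factor=config.dfa_factor)
    return {
        "alpha_table": alpha_df.to_dict(orient="records"),
        "series_length": n_ikis - config.discard_ikis,
        "alpha_anova": _anova_dict(anova),
        "surrogate": {
            "observed_f": surr.observed_f,
            "equivalent_p": surr.equivalent_p,
            "n_shuffles": surr.n_shuffles,
        },
        "_alpha_df": alpha_df,  # stripped before serialization
    }


def _anova_dict(anova) -> dict:
    out = {}
    for name, e in anova.effects.items():
        out[name] = {
            "F": e.f, "df": [e.df, e.df_error], "p": e.p,
            "gg_epsilon": e.gg_epsilon, "p_gg": e.p_gg,
            "p_reported": e.p_reported,
            "partial_eta_sq": e.partial_eta_sq,
            "mauchly_w": e.mauchly_w, "mauchly_p": e.mauchly_p,
            "sphericity_assumed": e.sphericity_assumed,
        }
    return out


def run_erp(config: RunConfig, rng_seed: int) -> dict:
    """ERP stage: simulate per-participant epochs, run the epoch chain,
    localize windows on the grand collapsed average, measure components."""
    ss = np.random.SeedSequence(rng_seed)
    child_seeds = [int(c.generate_state(1)[0] % (2**31 - 1))
                   for c in ss.spawn(config.n_participants)]

    per_participant: dict[str, dict] = {}
    for i, seed_i in enumerate(child_seeds):
        pid = f"P{i + 1:02d}"
        spec = default_erp_spec(
            n_epochs_per_cell=config.n_epochs_per_cell, seed=seed_i,
            noise_rms_uv=config.noise_rms_uv, participant_id=pid, fs=config.fs,
        )
        cells = simulate_epochs(spec)
        waveforms = {}
        for (prod, soa), eps in cells.items():
            waveforms[(prod, soa)] = process_epochs(
                eps,
                reject_threshold_uv=config.rejection_threshold_uv,
                drop_first=config.drop_initial_epochs,
            )
        cma = {soa: motor_correct(waveforms[("MA", soa)], waveforms[("MO", soa)])
               for soa in config.soa_levels}
        per_participant[pid] = {"av": {soa: waveforms[("AV", soa)]
                                       for soa in config.soa_levels},
                                "cma": cma}

    # collapsed localizer: equal-weight grand average over every analyzed
    # condition waveform (C-MA and AV, all SOAs, all participants)
    all_wfs = []
    for d in per_participant.values():
        all_wfs.extend(d["av"].values())
        all_wfs.extend(d["cma"].values())
    win_n1 = collapsed_localizer(all_wfs, "N1", list(config.n1_pool),
                                 config.n1_search_ms, config.component_width_ms)
    win_p2 = collapsed_localizer(all_wfs, "P2", list(config.p2_pool),
                                 config.p2_search_ms, config.component_width_ms)

    rows = []
    for pid, d in per_participant.items():
        for soa in config.soa_levels:
            for cond_label, wf in (("AV", d["av"][soa]), ("C-MA", d["cma"][soa])):
                for win in (win_n1, win_p2):
                    m = mean_amplitude(wf, win)
                    rows.append({
                        "participant": pid, "production": cond_label,
                        "soa": soa, "component": win.name,
                        "mean_amplitude_uv": m.mean_amplitude_uv,
                    })
    measures = pd.DataFrame(rows)

    component_results = {}
    for comp in ("N1", "P2"):
        sub = measures[measures.component == comp]
        anova = rm_anova_2x3(sub.rename(columns={"mean_amplitude_uv": "value"}))
        # per-SOA AV vs C-MA contrasts, BH-adjusted as a family
        contrasts = []
        for soa in config.soa_levels:
            av = sub[(sub.production == "AV") & (sub.soa == soa)] \
                .sort_values("participant")["mean_amplitude_uv"].to_numpy()
            cm = sub[(sub.production == "C-MA") & (sub.soa == soa)] \
                .sort_values("participant")["mean_amplitude_uv"].to_numpy()
            contrasts.append(paired_contrast(av, cm, label=f"AV-{soa} vs C-MA-{soa}"))
        adjust_contrasts(contrasts)
        # difference waves (C-MA minus AV) compared across SOA levels
        diff = {
            soa: (sub[(sub.production == "C-MA") & (sub.soa == soa)]
                  .sort_values("participant")["mean_amplitude_uv"].to_numpy()
                  - sub[(sub.production == "AV") & (sub.soa == soa)]
                  .sort_values("participant")["mean_amplitude_uv"].to_numpy())
            for soa in config.soa_levels
        }
        soas = list(config.soa_levels)
        dcontrasts = [
            paired_contrast(diff[s2], diff[s1], label=f"diff {s2} vs {s1}")
            for i, s1 in enumerate(soas) for s2 in soas[i + 1:]
        ]
        adjust_contrasts(dcontrasts)
        component_results[comp] = {
            "anova": _anova_dict(anova),
            "contrasts": [asdict(c) for c in contrasts],
            "difference_wave_contrasts": [asdict(c) for c in dcontrasts],
        }

    return {
        "windows": {
            "N1": {"center_ms": win_n1.center_ms, "width_ms": win_n1.width_ms,
                   "pool": win_n1.electrode_pool},
            "P2": {"center_ms": win_p2.center_ms, "width_ms": win_p2.width_ms,
                   "pool": win_p2.electrode_pool},
        },
        "measures": measures.to_dict(orient="records"),
        "components": component_results,
        "_measures_df": measures,
    }


def run_linking(alpha_df: pd.DataFrame, measures: pd.DataFrame,
                soa_levels) -> dict:
    """Random-intercept LMMs linking MA-condition α to component
    enhancement/attenuation, with the BIC Bayes factor for the α term."""
    ma = alpha_df[alpha_df.production == "MA"][
        ["participant", "soa", "alpha", "mean_iki_s"]
    ].rename(columns={"alpha": "alpha_ma", "mean_iki_s": "iki_ma"})

    out = {}
    for comp in ("N1", "P2"):
        sub = measures[measures.component == comp]
        cma = sub[sub.production == "C-MA"][
            ["participant", "soa", "mean_amplitude_uv"]
        ].rename(columns={"mean_amplitude_uv": "cma"})
        av = sub[sub.production == "AV"][
            ["participant", "soa", "mean_amplitude_uv"]
        ].rename(columns={"mean_amplitude_uv": "av"})
        joined = ma.merge(cma, on=["participant", "soa"]) \
                   .merge(av, on=["participant", "soa"]) \
                   .sort_values(["participant", "soa"])

        full = fit_random_intercept_lmm(
            joined["cma"], joined[["alpha_ma", "av", "iki_ma"]],
            joined["participant"],
        )
        reduced = fit_random_intercept_lmm(
            joined["cma"], joined[["av", "iki_ma"]], joined["participant"],
        )
        bf10 = bic_bayes_factor(reduced.bic, full.bic)
        out[comp] = {
            "model": f"{comp}_CMA ~ 1 + alpha_MA + {comp}_AV + IKI_MA"
                     " + (1 | participant)",
            "alpha_term": full.coef("alpha_ma"),
            "fixed_effects": {
                name: full.coef(name) for name in full.fixed_names
            },
            "var_intercept": full.var_intercept,
            "sd_intercept": full.sd_intercept,
            "var_residual": full.var_residual,
            "icc": full.icc,
            "loglik": full.loglik,
            "bic_full": full.bic,
            "bic_reduced": reduced.bic,
            "bf10_alpha": bf10,
            "boundary_fit": full.boundary,
            "n_obs": full.n_obs,
            "n_groups": full.n_groups,
        }
    return out


def run_full(config: RunConfig | None = None) -> dict:
    """Execute the whole pipeline and return the structured report.

    Re-running with an identical config reproduces every number bit for
    bit: all randomness descends from ``config.seed`` through fixed
    spawn offsets.
    """
    config = config or RunConfig()
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2)]

    behavior = run_behavior(config, stage_seeds[0])
    erp_out = run_erp(config, stage_seeds[1])
    linking = run_linking(behavior.pop("_alpha_df"), erp_out.pop("_measures_df"),
                          config.soa_levels)

    import pandas
    import scipy

    report = {
        "schema_version": SCHEMA_VERSION,
        "config": asdict(config),
        "provenance": {
            "config_hash": _config_hash(config),
            "package_version": __version__,
            "library_versions": {
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
            },
            "stage_seeds": {"behavior": stage_seeds[0], "erp": stage_seeds[1]},
        },
        "behavior": behavior,
        "erp": erp_out,
        "linking": linking,
    }
    return report


def validate_report(report: dict) -> None:
    """Schema check; raises ValueError on a malformed report."""
    missing = REPORT_REQUIRED_KEYS - set(report)
    if missing:
        raise ValueError(f"report missing keys: {sorted(missing)}")
    if report["schema_version"] != SCHEMA_VERSION:
        raise ValueError(f"unknown schema version {report['schema_version']!r}")
    for key in ("alpha_table", "alpha_anova", "surrogate"):
        if key not in report["behavior"]:
            raise ValueError(f"behavior section missing {key!r}")
    for key in ("windows", "measures", "components"):
        if key not in report["erp"]:
            raise ValueError(f"erp section missing {key!r}")
    for comp in ("N1", "P2"):
        if comp not in report["linking"]:
            raise ValueError(f"linking section missing {comp!r}")
        if "bf10_alpha" not in report["linking"][comp]:
            raise ValueError("linking model missing the alpha-term Bayes factor")


def report_to_json(report: dict, path) -> None:
    from .io import _jsonable

    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
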