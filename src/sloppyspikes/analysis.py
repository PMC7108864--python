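"""End-to-end sloppiness analysis of one spike dataset.

Composes the pipeline the individual modules implement: epoch the recording,
fit pairwise and independent maximum-entropy models per (ensemble, epoch),
compute Fisher information matrices and sensitivities, relate them to
cortical state, stimulus responses and functional-network topology, and
check parameter drift against stationary surrogates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import spike_io, state as state_mod, evoked as evoked_mod
from .fim import (
    FIMResult,
    aggregate_population_sensitivity,
    compute_fim,
    make_stationary_surrogates,
    median_split,
    projection_variance_by_rank,
    sensitivity_first_eig,
    sensitivity_weighted,
    split_half_sensitivity_reliability,
)
from .mem import (
    IndependentMaxEnt,
    PairwiseMaxEnt,
    empirical_distribution,
    js_divergence,
    kl_ratio,
)
from .network import build_graph, betweenness, population_coupling, topology_class_comparison
from .spike_io import EpochWindows, SpikeDataset

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "run_analysis", "fit_models", "sensitivity_tables"]


@dataclass
class AnalysisParams:
    """Tunable knobs of the full analysis; defaults follow the study design
    (N = 10 ensembles, 100-s epochs, 10-ms bins, alpha = 0.1, tol = 0.005,
    100 iterations, 1000 permutation resamples, 5000-pattern surrogates)."""

    n_ensemble_units: int = 10
    q_ensembles: int = 20
    epoch_s: float = 100.0
    pre_window_s: float = 1.5
    dt_s: float = 0.01
    silence_bin_s: float = 0.02
    mi_window_s: float = 0.5
    alpha: float = 0.1
    tol: float = 0.005
    max_iter: int = 100
    moment_method: str = "exact"
    n_mc: int = 100_000
    fim_method: str = "exact"
    fim_steps: int = 500_000
    n_perm: int = 1000
    surrogate_patterns: int = 5000


def _fit_params(p: AnalysisParams) -> dict:
    return dict(
        alpha=p.alpha,
        tol=p.tol,
        max_iter=p.max_iter,
        moment_method=p.moment_method,
        n_mc=p.n_mc,
    )


def fit_models(
    dataset: SpikeDataset,
    ew: EpochWindows,
    ensembles,
    params: AnalysisParams,
    seed: int | None = None,
) -> dict:
    """Fit pairwise + independent models for every (ensemble, valid epoch).

    Returns per-ensemble lists of fitted models, empirical distributions,
    goodness-of-fit divergences and parameter vectors."""
    valid = ew.valid_epochs
    rng_seq = np.random.SeedSequence(seed)
    out = {
        "valid_epochs": valid,
        "pairwise": [],
        "independent": [],
        "emp_dists": [],
        "djs_pair": [],
        "djs_ind": [],
        "kl_ratios": [],
        "omegas": [],
    }
    # binarize all single units once per epoch, reuse across ensembles
    rasters = {}
    for t in valid:
        rasters[t] = spike_io.binarize(
            dataset, ew.windows[t], dt=params.dt_s, units=dataset.single_unit_ids
        )
    for q, ens in enumerate(ensembles):
        pq, iq, dq, djp, dji, klr, om = [], [], [], [], [], [], []
        for t in valid:
            samples = spike_io.extract_patterns(rasters[t], ens, epoch=int(t))
            seed_t = int(rng_seq.spawn(1)[0].generate_state(1)[0] % 2**31)
            pair = PairwiseMaxEnt(random_state=seed_t, **_fit_params(params)).fit(samples)
            ind = IndependentMaxEnt(**_fit_params(params)).fit(samples)
            pdat = empirical_distribution(samples)
            ppair = pair.pattern_distribution()
            pind = ind.pattern_distribution()
            pq.append(pair)
            iq.append(ind)
            dq.append(pdat)
            djp.append(js_divergence(pdat, ppair))
            dji.append(js_divergence(pdat, pind))
            klr.append(kl_ratio(pdat, pind, ppair)[0])
            om.append(pair.theta_)
        out["pairwise"].append(pq)
        out["independent"].append(iq)
        out["emp_dists"].append(dq)
        out["djs_pair"].append(djp)
        out["djs_ind"].append(dji)
        out["kl_ratios"].append(klr)
        out["omegas"].append(np.array(om))
    return out


def compute_fims(fit_out: dict, params: AnalysisParams, seed: int | None = None):
    """FIM per (ensemble, epoch)."""
    ss = np.random.SeedSequence(seed)
    fims = []
    for models in fit_out["pairwise"]:
        row = []
        for m in models:
            s = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            row.append(
                compute_fim(
                    m, method=params.fim_method, n_steps=params.fim_steps, seed=s
                )
            )
        fims.append(row)
    return fims


def sensitivity_tables(fims, ensembles, single_unit_ids, weighted: bool = False):
    """Population sensitivity table with stiff/sloppy labels (all elements
    pooled, plus separate unit-level labels)."""
    measure = sensitivity_weighted if weighted else sensitivity_first_eig
    s_ne = [measure(row) for row in fims]
    table = aggregate_population_sensitivity(s_ne, ensembles, single_unit_ids)
    table["label"] = median_split(table["s"].to_numpy())
    units = table["kind"] == "unit"
    unit_labels = median_split(
        np.where(units, table["s"].to_numpy(), np.nan)
    )
    table["unit_label"] = unit_labels
    return table, s_ne


def run_analysis(
    dataset: SpikeDataset,
    params: AnalysisParams | None = None,
    seed: int | None = None,
) -> dict:
    """Run the full pipeline; returns a dictionary of results keyed by
    analysis (fits, sensitivities, state, evoked, network, surrogates)."""
    p = params or AnalysisParams()
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(6)]

    ew = spike_io.segment_epochs(dataset, p.epoch_s, p.pre_window_s)
    singles = np.sort(dataset.single_unit_ids)
    ensembles = spike_io.sample_ensembles(
        singles, p.n_ensemble_units, p.q_ensembles, seed=seeds[0]
    )
    fit_out = fit_models(dataset, ew, ensembles, p, seed=seeds[1])
    valid = fit_out["valid_epochs"]
    fims = compute_fims(fit_out, p, seed=seeds[2])

    # --- sloppiness spectrum and drift geometry
    eig_mean = np.mean(
        [[f.eigenvalues for f in row] for row in fims], axis=(0, 1)
    )
    tiny = np.max(eig_mean) * 1e-15
    eig_spread_log10 = float(
        np.log10(eig_mean[0] / max(eig_mean[-1], tiny))
    )
    profiles = [
        projection_variance_by_rank(row, om)
        for row, om in zip(fims, fit_out["omegas"])
    ]
    proj_profile = np.mean(profiles, axis=0)
    ranks = np.arange(1, proj_profile.size + 1)
    rho, rho_p = stats.spearmanr(ranks, proj_profile)

    # --- sensitivity maps
    table, s_ne = sensitivity_tables(fims, ensembles, singles)
    table_w, _ = sensitivity_tables(fims, ensembles, singles, weighted=True)
    table["s_weighted"] = table_w["s"]

    # --- cortical state
    cs = state_mod.silence_density(dataset, ew, bin_width=p.silence_bin_s)
    cs_valid = cs[valid]
    djs_mat = state_mod.pairwise_pattern_divergence(fit_out["emp_dists"])
    djs_state = state_mod.state_divergence_correlation(
        djs_mat, cs_valid, n_perm=p.n_perm, seed=seeds[3]
    )
    obs = state_mod.observable_timeseries(dataset, ew, unit_ids=singles, dt=p.dt_s)
    series = np.hstack([obs["rates"], obs["correlations"]])[valid]
    rcs = state_mod.state_observable_correlation(series, cs_valid)
    per_ens_pairs = []
    for s_vec, ens in zip(s_ne, ensembles):
        labels_ne = median_split(s_vec)
        rcs_ne = _ensemble_rcs(rcs, ens, singles)
        stiff = rcs_ne[(labels_ne == "stiff") & ~np.isnan(rcs_ne)]
        sloppy = rcs_ne[(labels_ne == "sloppy") & ~np.isnan(rcs_ne)]
        if stiff.size and sloppy.size:
            per_ens_pairs.append((float(stiff.mean()), float(sloppy.mean())))
    state_rel = state_mod.sensitivity_state_relation(
        rcs,
        table["s"].to_numpy(),
        labels=table["label"].to_numpy(),
        per_ensemble_pairs=per_ens_pairs,
    )

    # --- evoked responses
    counts = evoked_mod.trial_counts(
        dataset, ew, unit_ids=singles, pre=p.mi_window_s, post=p.mi_window_s
    )
    mi_epochs = evoked_mod.modulation_index(counts["rspon"], counts["rstim"])
    mi_session = np.nanmean(mi_epochs, axis=0)
    units_mask = (table["kind"] == "unit").to_numpy()
    s_units = table.loc[units_mask, "s"].to_numpy()
    unit_labels = table.loc[units_mask, "unit_label"].to_numpy()
    mi_rel = evoked_mod.mi_sensitivity_relation(mi_session, s_units)
    ev_medians = []
    for q, ens in enumerate(ensembles):
        pos = np.searchsorted(singles, ens)
        res = evoked_mod.mi_eigvec_correlation(mi_epochs[np.ix_(valid, pos)], fims[q])
        ev_medians.append(res["median"])
    sign_p = evoked_mod.sign_test_negative(ev_medians)
    covered_units = unit_labels != ""
    delta_mi = evoked_mod.delta_mi_by_state(
        mi_epochs[np.ix_(valid, covered_units)],
        unit_labels[covered_units],
        cs_valid,
    )

    # --- network topology
    net = build_graph(obs["correlations"][valid], unit_ids=singles)
    bc = betweenness(net["graph"])
    bc_arr = np.array([bc[int(u)] for u in singles], dtype=float)
    rasters = [
        spike_io.binarize(dataset, ew.windows[t], dt=p.dt_s, units=singles)
        for t in valid
    ]
    coupling = population_coupling(rasters)
    rates_session = np.nanmean(obs["rates"][valid], axis=0)
    link_mask = (table["kind"] == "pair").to_numpy()
    link_labels = table.loc[link_mask, "label"].to_numpy()
    link_mean_r = np.nanmean(obs["correlations"][valid], axis=0)
    auc_tab = topology_class_comparison(
        {"rate": rates_session, "bc": bc_arr, "coupling": coupling},
        unit_labels,
        n_perm=p.n_perm,
        seed=seeds[4],
    )
    if (link_labels == "stiff").any() and (link_labels == "sloppy").any():
        auc_links = topology_class_comparison(
            {"link_correlation": link_mean_r},
            link_labels,
            n_perm=p.n_perm,
            seed=seeds[4] + 1,
        )
        auc_tab = pd.concat([auc_tab, auc_links], ignore_index=True)
    bc_rate_rc = float(stats.pearsonr(bc_arr, rates_session)[0])

    # --- stationary surrogates (reference: ensemble 0, middle epoch)
    ref = fit_out["pairwise"][0][len(valid) // 2]
    sur = make_stationary_surrogates(
        ref,
        n_epochs=len(valid),
        n_patterns=p.surrogate_patterns,
        seed=seeds[5],
        fim_method=p.fim_method,
    )
    sur_profile = projection_variance_by_rank(sur["fims"], sur["omegas"])
    data_ratio = float(proj_profile[-1] / proj_profile[0])
    sur_ratio = float(sur_profile[-1] / sur_profile[0])

    reliability = split_half_sensitivity_reliability(fims, ensembles, singles)

    flat = lambda lol: np.array([v for row in lol for v in row])
    return {
        "params": p,
        "epoch_windows": ew,
        "ensembles": ensembles,
        "fits": fit_out,
        "fims": fims,
        "sensitivity_table": table,
        "s_ne": s_ne,
        "eig_spread_log10": eig_spread_log10,
        "projection_profile": proj_profile,
        "projection_rank_spearman": (float(rho), float(rho_p)),
        "surrogate_profile": sur_profile,
        "projection_ratio": {"data": data_ratio, "surrogate": sur_ratio},
        "cs": cs,
        "djs_matrix": djs_mat,
        "djs_state": djs_state,
        "rcs": rcs,
        "state_relation": state_rel,
        "mi_epochs": mi_epochs,
        "mi_session": mi_session,
        "mi_relation": mi_rel,
        "mi_eigvec_medians": ev_medians,
        "mi_eigvec_sign_p": sign_p,
        "delta_mi": delta_mi,
        "network": net,
        "bc": bc_arr,
        "coupling": coupling,
        "rates": rates_session,
        "auc_table": auc_tab,
        "bc_rate_correlation": bc_rate_rc,
        "split_half_reliability": reliability,
        "djs_pair_all": flat(fit_out["djs_pair"]),
        "djs_ind_all": flat(fit_out["djs_ind"]),
        "kl_ratio_all": flat(fit_out["kl_ratios"]),
        "pairwise_better_fraction": float(
            np.mean(flat(fit_out["djs_pair"]) < flat(fit_out["djs_ind"]))
        ),
        "convergence_fraction": float(
            np.mean([m.converged_ for row in fit_out["pairwise"] for m in row])
        ),
    }


def _ensemble_rcs(rcs: np.ndarray, ens: np.ndarray, singles: np.ndarray) -> np.ndarray:
    """Map the population rcs vector onto one ensemble's 55 elements."""
    n_units = singles.size
    pos = np.searchsorted(singles, ens)
    n = ens.size
    out = np.empty(n + n * (n - 1) // 2)
    out[:n] = rcs[pos]
    # population pair column index for sorted units a < b (row-major triu)
    def pair_col(a, b):
        if a > b:
            a, b = b, a
        return n_units + a * n_units - a * (a + 1) // 2 + (b - a - 1)

    k = n
    for i in range(n):
        for j in range(i + 1, n):
            out[k] = rcs[pair_col(int(pos[i]), int(pos[j]))]
            k += 1
    return out
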