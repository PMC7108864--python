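"""Staged pipeline with a run directory, manifest and CSV/JSON artifacts.

Stages (in dependency order): simulate -> fit -> fim -> {state, evoked,
network, surrogate} -> classify -> report.  Each stage reads the artifacts
of its upstream stages from the run directory and writes its own; a missing
upstream artifact raises an error naming the stage that produces it.
Re-running a stage with identical config and seed reproduces identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import analysis, evoked as evoked_mod, spike_io, state as state_mod
from .analysis import AnalysisParams
from .fim import (
    FIMResult,
    make_stationary_surrogates,
    median_split,
    projection_variance_by_rank,
)
from .mem import PairwiseMaxEnt, empirical_distribution, js_divergence
from .network import betweenness, build_graph, population_coupling, topology_class_comparison
from .synth import GeneratorConfig, emulation_report, generate

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "fit",
    "fim",
    "state",
    "evoked",
    "network",
    "classify",
    "surrogate",
    "report",
)

# which stage produces which artifact (for actionable errors)
_PRODUCERS = {
    "spikes.csv": "simulate",
    "truth.json": "simulate",
    "models.json": "fit",
    "fim.npz": "fim",
    "sensitivity.csv": "fim",
    "state.csv": "state",
    "rcs.csv": "state",
    "state_relation.json": "state",
    "evoked.csv": "evoked",
    "mi_relation.json": "evoked",
    "bc.csv": "network",
    "edges.csv": "network",
    "auc.csv": "classify",
    "surrogate.json": "surrogate",
}


@dataclass
class RunConfig:
    """Full run configuration: analysis knobs + generator settings.

    All analysis defaults equal the study's stated values (see
    AnalysisParams); the generator defaults are the emulated study
    conditions."""

    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_spikes: str | None = None  # use an existing spike table instead

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        ana = AnalysisParams(**raw.get("analysis", {}))
        gen = GeneratorConfig(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.get("generator", {}).items()
            }
        )
        return cls(analysis=ana, generator=gen, input_spikes=raw.get("input_spikes"))

    def to_dict(self) -> dict:
        d = {
            "analysis": dataclasses.asdict(self.analysis),
            "generator": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.generator).items()
            },
            "input_spikes": self.input_spikes,
        }
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class MissingArtifactError(FileNotFoundError):
    pass


def _require(out_dir: Path, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = out_dir / name
        if not p.exists():
            raise MissingArtifactError(
                f"missing artifact {name!r}; run stage "
                f"{_PRODUCERS.get(name, '?')!r} first"
            )
        paths.append(p)
    return paths


def _update_manifest(out_dir: Path, stage: str, config: RunConfig, seed) -> None:
    path = out_dir / "manifest.json"
    manifest = {}
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest.setdefault("config_digest", config.digest())
    manifest["config"] = config.to_dict()
    stages = manifest.setdefault("stages", {})
    stages[stage] = {"seed": seed}
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _stage_seed(seed: int | None, stage: str) -> int | None:
    if seed is None:
        return None
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _load_dataset(config: RunConfig, out_dir: Path) -> spike_io.SpikeDataset:
    if config.input_spikes:
        return spike_io.read_spike_table(config.input_spikes)
    (path,) = _require(out_dir, "spikes.csv")
    return spike_io.read_spike_table(path)


def _load_models(out_dir: Path, config: RunConfig):
    (path,) = _require(out_dir, "models.json")
    payload = json.loads(path.read_text())
    valid = np.array(payload["valid_epochs"])
    ensembles = [np.array(e) for e in payload["ensembles"]]
    models = []
    for ens, row in zip(ensembles, payload["models"]):
        models.append(
            [
                PairwiseMaxEnt.from_parameters(
                    m["h"], m["J"], unit_ids=ens, epoch=t
                )
                for m, t in zip(row, valid)
            ]
        )
    return payload, valid, ensembles, models


def run_stage(stage: str, config: RunConfig, out_dir, seed: int | None = None) -> list[str]:
    """Execute one stage; returns the artifact filenames written."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sseed = _stage_seed(seed, stage)
    written = _DISPATCH[stage](config, out_dir, sseed)
    _update_manifest(out_dir, stage, config, seed)
    return written


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(config: RunConfig, out_dir: Path, seed) -> list[str]:
    dataset, truth = generate(config.generator, seed=seed)
    spike_io.write_spike_table(dataset, out_dir / "spikes.csv")
    truth.to_json(out_dir / "truth.json")
    report = emulation_report(dataset, truth)
    report.to_csv(out_dir / "emulation_report.csv", index=False)
    return ["spikes.csv", "spikes.events.csv", "truth.json", "emulation_report.csv"]


def _stage_fit(config: RunConfig, out_dir: Path, seed) -> list[str]:
    p = config.analysis
    dataset = _load_dataset(config, out_dir)
    ew = spike_io.segment_epochs(dataset, p.epoch_s, p.pre_window_s)
    singles = np.sort(dataset.single_unit_ids)
    ensembles = spike_io.sample_ensembles(
        singles, p.n_ensemble_units, p.q_ensembles, seed=seed
    )
    fit_out = analysis.fit_models(dataset, ew, ensembles, p, seed=seed)
    payload = {
        "valid_epochs": [int(t) for t in fit_out["valid_epochs"]],
        "ensembles": [[int(u) for u in e] for e in ensembles],
        "models": [
            [
                {
                    "h": m.h_.tolist(),
                    "J": m.J_.tolist(),
                    "h_independent": ind.h_.tolist(),
                    "converged": bool(m.converged_),
                    "discrepancy": float(m.discrepancy_),
                    "djs_pairwise": float(djp),
                    "djs_independent": float(dji),
                    "kl_ratio": float(klr),
                }
                for m, ind, djp, dji, klr in zip(
                    fit_out["pairwise"][q],
                    fit_out["independent"][q],
                    fit_out["djs_pair"][q],
                    fit_out["djs_ind"][q],
                    fit_out["kl_ratios"][q],
                )
            ]
            for q in range(len(ensembles))
        ],
    }
    (out_dir / "models.json").write_text(json.dumps(payload))
    return ["models.json"]


def _stage_fim(config: RunConfig, out_dir: Path, seed) -> list[str]:
    payload, valid, ensembles, models = _load_models(out_dir, config)
    p = config.analysis
    fit_like = {"pairwise": models}
    fims = analysis.compute_fims(fit_like, p, seed=seed)
    q_n, t_n = len(models), len(valid)
    n_par = fims[0][0].n_params
    eigvals = np.empty((q_n, t_n, n_par))
    eigvecs = np.empty((q_n, t_n, n_par, n_par))
    omegas = np.empty((q_n, t_n, n_par))
    for q in range(q_n):
        for t in range(t_n):
            eigvals[q, t] = fims[q][t].eigenvalues
            eigvecs[q, t] = fims[q][t].eigenvectors
            omegas[q, t] = models[q][t].theta_
    np.savez_compressed(
        out_dir / "fim.npz", eigenvalues=eigvals, eigenvectors=eigvecs, omegas=omegas
    )
    dataset = _load_dataset(config, out_dir)
    singles = np.sort(dataset.single_unit_ids)
    table, _ = analysis.sensitivity_tables(fims, ensembles, singles)
    table_w, _ = analysis.sensitivity_tables(fims, ensembles, singles, weighted=True)
    table["s_weighted"] = table_w["s"]
    table_out = table.copy()
    table_out["members"] = table_out["members"].apply(
        lambda m: "-".join(str(x) for x in m)
    )
    table_out.to_csv(out_dir / "sensitivity.csv", index=False)
    return ["fim.npz", "sensitivity.csv"]


def _recover_fims(out_dir: Path):
    (path,) = _require(out_dir, "fim.npz")
    with np.load(path) as z:
        eigvals, eigvecs, omegas = z["eigenvalues"], z["eigenvectors"], z["omegas"]
    fims = [
        [
            FIMResult(
                fim=np.empty((0, 0)),
                eigenvalues=eigvals[q, t],
                eigenvectors=eigvecs[q, t],
            )
            for t in range(eigvals.shape[1])
        ]
        for q in range(eigvals.shape[0])
    ]
    return fims, omegas


def _stage_state(config: RunConfig, out_dir: Path, seed) -> list[str]:
    p = config.analysis
    dataset = _load_dataset(config, out_dir)
    payload, valid, ensembles, models = _load_models(out_dir, config)
    ew = spike_io.segment_epochs(dataset, p.epoch_s, p.pre_window_s)
    cs = state_mod.silence_density(dataset, ew, bin_width=p.silence_bin_s)
    pd.DataFrame({"epoch": np.arange(ew.n_epochs), "cs": cs}).to_csv(
        out_dir / "state.csv", index=False
    )
    singles = np.sort(dataset.single_unit_ids)
    dists = []
    rasters = {
        t: spike_io.binarize(dataset, ew.windows[t], dt=p.dt_s, units=singles)
        for t in valid
    }
    for ens in ensembles:
        dists.append(
            [
                empirical_distribution(spike_io.extract_patterns(rasters[t], ens))
                for t in valid
            ]
        )
    djs_mat = state_mod.pairwise_pattern_divergence(dists)
    rel = state_mod.state_divergence_correlation(
        djs_mat, cs[valid], n_perm=p.n_perm, seed=seed
    )
    obs = state_mod.observable_timeseries(dataset, ew, unit_ids=singles, dt=p.dt_s)
    series = np.hstack([obs["rates"], obs["correlations"]])[valid]
    rcs = state_mod.state_observable_correlation(series, cs[valid])
    sens = pd.read_csv(*_require(out_dir, "sensitivity.csv"))
    sens["rcs"] = rcs
    sens.to_csv(out_dir / "rcs.csv", index=False)
    srel = state_mod.sensitivity_state_relation(
        rcs, sens["s"].to_numpy(), labels=sens["label"].fillna("").to_numpy()
    )
    (out_dir / "state_relation.json").write_text(
        json.dumps({"djs_vs_state": {"rc": rel["rc"], "p": rel["p"]}, "rcs_vs_s": srel})
    )
    return ["state.csv", "rcs.csv", "state_relation.json"]


def _stage_evoked(config: RunConfig, out_dir: Path, seed) -> list[str]:
    p = config.analysis
    dataset = _load_dataset(config, out_dir)
    sens = pd.read_csv(*_require(out_dir, "sensitivity.csv"))
    ew = spike_io.segment_epochs(dataset, p.epoch_s, p.pre_window_s)
    singles = np.sort(dataset.single_unit_ids)
    counts = evoked_mod.trial_counts(
        dataset, ew, unit_ids=singles, pre=p.mi_window_s, post=p.mi_window_s
    )
    mi = evoked_mod.modulation_index(counts["rspon"], counts["rstim"])
    signs = evoked_mod.response_sign(counts["rspon"], counts["rstim"])
    rows = []
    for e in range(ew.n_epochs):
        for u, uid in enumerate(singles):
            rows.append(
                {
                    "unit_id": int(uid),
                    "epoch": e,
                    "rspon": counts["rspon"][e, u],
                    "rstim": counts["rstim"][e, u],
                    "mi": mi[e, u],
                    "sign": signs[u],
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "evoked.csv", index=False)
    units = sens[sens["kind"] == "unit"]
    s_units = units["s"].to_numpy()
    mi_session = np.nanmean(mi, axis=0)
    rel = evoked_mod.mi_sensitivity_relation(mi_session, s_units)
    labels = units["unit_label"].fillna("").to_numpy()
    covered = labels != ""
    cs = pd.read_csv(*_require(out_dir, "state.csv"))["cs"].to_numpy()
    valid = ew.valid_epochs
    delta = evoked_mod.delta_mi_by_state(
        mi[np.ix_(valid, covered)], labels[covered], cs[valid]
    )
    delta.to_csv(out_dir / "delta_mi.csv", index=False)
    (out_dir / "mi_relation.json").write_text(json.dumps(rel))
    return ["evoked.csv", "delta_mi.csv", "mi_relation.json"]


def _stage_network(config: RunConfig, out_dir: Path, seed) -> list[str]:
    p = config.analysis
    dataset = _load_dataset(config, out_dir)
    sens = pd.read_csv(*_require(out_dir, "sensitivity.csv"))
    ew = spike_io.segment_epochs(dataset, p.epoch_s, p.pre_window_s)
    singles = np.sort(dataset.single_unit_ids)
    valid = ew.valid_epochs
    obs = state_mod.observable_timeseries(dataset, ew, unit_ids=singles, dt=p.dt_s)
    net = build_graph(obs["correlations"][valid], unit_ids=singles)
    net["edges"].to_csv(out_dir / "edges.csv", index=False)
    bc = betweenness(net["graph"])
    rasters = [
        spike_io.binarize(dataset, ew.windows[t], dt=p.dt_s, units=singles)
        for t in valid
    ]
    coupling = population_coupling(rasters)
    rates = np.nanmean(obs["rates"][valid], axis=0)
    units = sens[sens["kind"] == "unit"]
    pd.DataFrame(
        {
            "unit_id": singles,
            "bc": [bc[int(u)] for u in singles],
            "coupling": coupling,
            "rate": rates,
            "s": units["s"].to_numpy(),
            "label": units["unit_label"].fillna("").to_numpy(),
        }
    ).to_csv(out_dir / "bc.csv", index=False)
    return ["edges.csv", "bc.csv"]


def _stage_classify(config: RunConfig, out_dir: Path, seed) -> list[str]:
    p = config.analysis
    tab = pd.read_csv(*_require(out_dir, "bc.csv"))
    labels = tab["label"].fillna("").to_numpy()
    auc = topology_class_comparison(
        {
            "rate": tab["rate"].to_numpy(),
            "bc": tab["bc"].to_numpy(),
            "coupling": tab["coupling"].to_numpy(),
        },
        labels,
        n_perm=p.n_perm,
        seed=seed,
    )
    auc.to_csv(out_dir / "auc.csv", index=False)
    return ["auc.csv"]


def _stage_surrogate(config: RunConfig, out_dir: Path, seed) -> list[str]:
    p = config.analysis
    payload, valid, ensembles, models = _load_models(out_dir, config)
    fims, omegas = _recover_fims(out_dir)
    profiles = [
        projection_variance_by_rank(fims[q], omegas[q]) for q in range(len(fims))
    ]
    data_profile = np.mean(profiles, axis=0)
    ref = models[0][len(valid) // 2]
    ref.set_params(
        alpha=p.alpha, tol=p.tol, max_iter=p.max_iter, moment_method=p.moment_method
    )
    sur = make_stationary_surrogates(
        ref,
        n_epochs=len(valid),
        n_patterns=p.surrogate_patterns,
        seed=seed,
        fim_method=p.fim_method,
    )
    sur_profile = projection_variance_by_rank(sur["fims"], sur["omegas"])
    out = {
        "data_profile": data_profile.tolist(),
        "surrogate_profile": sur_profile.tolist(),
        "data_ratio_last_first": float(data_profile[-1] / data_profile[0]),
        "surrogate_ratio_last_first": float(sur_profile[-1] / sur_profile[0]),
    }
    (out_dir / "surrogate.json").write_text(json.dumps(out))
    return ["surrogate.json"]


def _stage_report(config: RunConfig, out_dir: Path, seed) -> list[str]:
    payload, valid, ensembles, models = _load_models(out_dir, config)
    fims, omegas = _recover_fims(out_dir)
    eig_mean = np.mean(
        [[f.eigenvalues for f in row] for row in fims], axis=(0, 1)
    )
    spread = float(np.log10(eig_mean[0] / max(eig_mean[-1], eig_mean[0] * 1e-15)))
    profiles = [
        projection_variance_by_rank(fims[q], omegas[q]) for q in range(len(fims))
    ]
    profile = np.mean(profiles, axis=0)
    rho, rho_p = stats.spearmanr(np.arange(1, profile.size + 1), profile)
    djs_pair = [m["djs_pairwise"] for row in payload["models"] for m in row]
    djs_ind = [m["djs_independent"] for row in payload["models"] for m in row]
    report = {
        "n_models": len(djs_pair),
        "eigenvalue_spread_log10": spread,
        "projection_rank_spearman": float(rho),
        "projection_rank_spearman_p": float(rho_p),
        "pairwise_better_fraction": float(
            np.mean(np.array(djs_pair) < np.array(djs_ind))
        ),
        "kl_ratio_mean": float(
            np.nanmean([m["kl_ratio"] for row in payload["models"] for m in row])
        ),
    }
    for name in ("state_relation.json", "mi_relation.json", "surrogate.json"):
        path = out_dir / name
        if path.exists():
            report[name.removesuffix(".json")] = json.loads(path.read_text())
    path = out_dir / "auc.csv"
    if path.exists():
        report["auc"] = pd.read_csv(path).to_dict(orient="records")
    (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return ["report.json"]


_DISPATCH = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "fim": _stage_fim,
    "state": _stage_state,
    "evoked": _stage_evoked,
    "network": _stage_network,
    "classify": _stage_classify,
    "surrogate": _stage_surrogate,
    "report": _stage_report,
}
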