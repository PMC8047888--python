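"""Readers/writers for the interchange formats.

All files are UTF-8 CSV with a mandatory header row and dot decimal
separator.

* removal records: long format ``unit_id, year, effort_trap_days,
  captures`` — an absent (unit, year) row means no trapping that year;
* covariates: ``unit_id, paddy, dry_crop, slope, flow_accum, road``;
* adjacency: undirected deduplicated edge list ``unit_id_a, unit_id_b``;
* allocations: ``unit_id, effort_trap_days``;
* posterior draws: one row per retained draw, columns
  ``alpha, lambda, beta1..beta6, gamma, sigma_*, rho[i], omega[t],
  mu[i,t]`` plus a JSON sidecar with the run metadata (chains, warmup,
  thinning, R-hat, seed).

Internal unit indexing is the row order of the covariates file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium import Allocation
from .model import PosteriorSamples
from .network import RiverNetwork, COVARIATE_NAMES, standardize_columns
from .simulate import RemovalDataset, TrueParameters


class LoadError(ValueError):
    """A file failed validation; the message lists the offending records."""


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def load_dataset(removal_csv, covariates_csv, adjacency_csv,
                 standardize: bool = False):
    """Load and validate the three input files.

    Returns ``(dataset, network)``.  With ``standardize=True``, covariate
    columns that are not already mean-0/SD-1 are re-standardized.
    """
    cov = pd.read_csv(covariates_csv, dtype={"unit_id": str})
    if "unit_id" not in cov.columns or cov.shape[1] < 2:
        raise LoadError("covariates file needs unit_id plus covariate columns")
    unit_ids = tuple(cov["unit_id"])
    index = {u: i for i, u in enumerate(unit_ids)}
    H = cov.drop(columns="unit_id").to_numpy(dtype=float)
    if standardize:
        if not (np.allclose(H.mean(0), 0, atol=1e-8) and np.allclose(H.std(0), 1, atol=1e-8)):
            H = standardize_columns(H)

    adj = pd.read_csv(adjacency_csv, dtype=str)
    need = {"unit_id_a", "unit_id_b"}
    if not need.issubset(adj.columns):
        raise LoadError(f"adjacency file needs columns {sorted(need)}")
    unknown = sorted(
        set(adj["unit_id_a"]).union(adj["unit_id_b"]) - set(unit_ids)
    )
    if unknown:
        raise LoadError(f"adjacency references unknown unit ids: {unknown}")
    edges = tuple((index[a], index[b]) for a, b in zip(adj["unit_id_a"], adj["unit_id_b"]))
    network = RiverNetwork(unit_ids=unit_ids, covariates=H, edges=edges)

    rec = pd.read_csv(removal_csv, dtype={"unit_id": str})
    need = {"unit_id", "year", "effort_trap_days", "captures"}
    if not need.issubset(rec.columns):
        raise LoadError(f"removal file needs columns {sorted(need)}")
    unknown = sorted(set(rec["unit_id"]) - set(unit_ids))
    if unknown:
        raise LoadError(f"removal records reference unknown unit ids: {unknown}")
    dup = rec.duplicated(subset=["unit_id", "year"])
    if dup.any():
        bad = rec.loc[dup, ["unit_id", "year"]].to_records(index=False).tolist()
        raise LoadError(f"duplicate (unit, year) rows: {bad}")
    if (rec["effort_trap_days"] < 0).any() or (rec["captures"] < 0).any():
        raise LoadError("negative effort or captures")
    zero_e = rec["effort_trap_days"] == 0
    if (rec.loc[zero_e, "captures"] > 0).any():
        bad = rec.loc[zero_e & (rec["captures"] > 0), ["unit_id", "year"]]
        raise LoadError(f"captures > 0 with zero effort: {bad.to_records(index=False).tolist()}")

    years = tuple(sorted(rec["year"].unique()))
    ycol = {y: t for t, y in enumerate(years)}
    I, T = len(unit_ids), len(years)
    E = np.full((I, T), np.nan)
    C = np.full((I, T), np.nan)
    for row in rec.itertuples(index=False):
        i, t = index[row.unit_id], ycol[row.year]
        E[i, t] = row.effort_trap_days
        C[i, t] = row.captures
    dataset = RemovalDataset(network=network, years=years, effort=E, captures=C)
    return dataset, network


def save_dataset(dataset: RemovalDataset, removal_csv, covariates_csv, adjacency_csv):
    """Write the three CSVs; inverse of :func:`load_dataset`."""
    net = dataset.network
    rows = []
    for i, u in enumerate(net.unit_ids):
        for t, y in enumerate(dataset.years):
            if not np.isnan(dataset.effort[i, t]):
                rows.append((u, y, dataset.effort[i, t], int(dataset.captures[i, t])))
    pd.DataFrame(rows, columns=["unit_id", "year", "effort_trap_days", "captures"]) \
        .to_csv(removal_csv, index=False)
    names = COVARIATE_NAMES if net.covariates.shape[1] == len(COVARIATE_NAMES) \
        else [f"cov{j + 1}" for j in range(net.covariates.shape[1])]
    cov = pd.DataFrame(net.covariates, columns=list(names))
    cov.insert(0, "unit_id", list(net.unit_ids))
    cov.to_csv(covariates_csv, index=False)
    pd.DataFrame(
        [(net.unit_ids[a], net.unit_ids[b]) for a, b in net.edges],
        columns=["unit_id_a", "unit_id_b"],
    ).to_csv(adjacency_csv, index=False)


# ---------------------------------------------------------------------------
# truth dump (generator output for recovery tests)
# ---------------------------------------------------------------------------

def save_truth(params: TrueParameters, mu: np.ndarray, truth_json, mu_csv):
    payload = {
        "alpha": params.alpha, "lambda": params.lam,
        "beta": list(map(float, params.beta)), "beta6": params.beta6,
        "gamma": params.gamma, "sigma_rho": params.sigma_rho,
        "sigma_omega": params.sigma_omega, "sigma_e": params.sigma_e,
        "sigma_1": params.sigma_1,
        "rho": None if params.rho is None else list(map(float, params.rho)),
        "omega": None if params.omega is None else list(map(float, params.omega)),
    }
    Path(truth_json).write_text(json.dumps(payload, indent=1))
    pd.DataFrame(mu).to_csv(mu_csv, index=False)


def load_truth(truth_json, mu_csv):
    d = json.loads(Path(truth_json).read_text())
    params = TrueParameters(
        alpha=d["alpha"], lam=d["lambda"], beta=np.array(d["beta"]),
        beta6=d["beta6"], gamma=d["gamma"], sigma_rho=d["sigma_rho"],
        sigma_omega=d["sigma_omega"], sigma_e=d["sigma_e"], sigma_1=d["sigma_1"],
        rho=None if d["rho"] is None else np.array(d["rho"]),
        omega=None if d["omega"] is None else np.array(d["omega"]),
    )
    mu = pd.read_csv(mu_csv).to_numpy(dtype=float)
    return params, mu


# ---------------------------------------------------------------------------
# posterior draws
# ---------------------------------------------------------------------------

def _posterior_columns(I: int, T: int):
    cols = ["alpha", "lambda"] + [f"beta{j}" for j in range(1, 7)] + [
        "gamma", "sigma_rho", "sigma_omega", "sigma_e", "sigma_1"]
    cols += [f"rho[{i + 1}]" for i in range(I)]
    cols += [f"omega[{t + 1}]" for t in range(T - 1)]
    cols += [f"mu[{i + 1},{t + 1}]" for i in range(I) for t in range(T)]
    return cols


def save_posterior(samples: PosteriorSamples, path):
    """Write draws to CSV (full float precision) plus ``<path>.meta.json``."""
    path = Path(path)
    N = samples.n_draws
    I, T = samples.mu.shape[1], samples.mu.shape[2]
    mat = np.column_stack([
        samples.alpha, samples.lam, samples.beta, samples.beta6,
        samples.gamma, samples.sigma_rho, samples.sigma_omega,
        samples.sigma_e, samples.sigma_1, samples.rho, samples.omega,
        samples.mu.reshape(N, I * T),
    ])
    pd.DataFrame(mat, columns=_posterior_columns(I, T)).to_csv(
        path, index=False, float_format="%.17g")
    meta = {
        "n_chains": samples.n_chains, "n_warmup": samples.n_warmup,
        "n_kept": samples.n_kept, "thin": samples.thin,
        "rhat": samples.rhat, "converged": samples.converged,
        "seed": samples.seed, "n_units": I, "n_years": T,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_posterior(path) -> PosteriorSamples:
    """Lossless counterpart of :func:`save_posterior`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise LoadError(f"posterior file unreadable (truncated?): {exc}") from exc
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    I = meta.get("n_units") or sum(c.startswith("rho[") for c in df.columns)
    T = meta.get("n_years") or (sum(c.startswith("mu[") for c in df.columns) // I)
    expected = _posterior_columns(I, T)
    missing = sorted(set(expected) - set(df.columns))
    if missing:
        raise LoadError(f"posterior file missing columns: {missing[:8]}"
                        + ("..." if len(missing) > 8 else ""))
    if df[expected].isna().any().any():
        raise LoadError("posterior file contains missing values (truncated file?)")
    N = len(df)
    return PosteriorSamples(
        alpha=df["alpha"].to_numpy(), lam=df["lambda"].to_numpy(),
        beta=df[[f"beta{j}" for j in range(1, 6)]].to_numpy(),
        beta6=df["beta6"].to_numpy(), gamma=df["gamma"].to_numpy(),
        sigma_rho=df["sigma_rho"].to_numpy(),
        sigma_omega=df["sigma_omega"].to_numpy(),
        sigma_e=df["sigma_e"].to_numpy(), sigma_1=df["sigma_1"].to_numpy(),
        rho=df[[f"rho[{i + 1}]" for i in range(I)]].to_numpy(),
        omega=df[[f"omega[{t + 1}]" for t in range(T - 1)]].to_numpy(),
        mu=df[[f"mu[{i + 1},{t + 1}]" for i in range(I) for t in range(T)]]
            .to_numpy().reshape(N, I, T),
        n_chains=meta.get("n_chains", 1), n_warmup=meta.get("n_warmup", 0),
        n_kept=meta.get("n_kept", N), thin=meta.get("thin", 1),
        rhat=meta.get("rhat", {}), converged=meta.get("converged", True),
        seed=meta.get("seed"),
    )


# ---------------------------------------------------------------------------
# allocations
# ---------------------------------------------------------------------------

def save_allocation(allocation: Allocation, network: RiverNetwork, path):
    pd.DataFrame({
        "unit_id": list(network.unit_ids),
        "effort_trap_days": allocation.effort,
    }).to_csv(path, index=False, float_format="%.17g")


def load_allocation(path, network: RiverNetwork) -> Allocation:
    df = pd.read_csv(path, dtype={"unit_id": str})
    need = {"unit_id", "effort_trap_days"}
    if not need.issubset(df.columns):
        raise LoadError(f"allocation file needs columns {sorted(need)}")
    order = {u: i for i, u in enumerate(network.unit_ids)}
    unknown = sorted(set(df["unit_id"]) - set(order))
    if unknown or len(df) != network.n_units:
        raise LoadError(f"allocation units do not match network (unknown: {unknown})")
    e = np.zeros(network.n_units)
    for row in df.itertuples(index=False):
        e[order[row.unit_id]] = row.effort_trap_days
    return Allocation.from_effort(e)
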