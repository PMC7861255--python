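"""Monte-Carlo replication harness, aggregation, and the GLM analysis.

A :class:`SimulationConfig` fixes one cell of the experimental grid (network
type and size, agent model, content type, placement).  Each replicate draws a
fresh network and a fresh agent population from a replicate-specific random
stream, runs one cascade from the most central node, and yields one
:class:`RunRecord`-shaped row.  The replicate stream is derived as
``SeedSequence(base_seed, spawn_key=(replicate,))`` — a fixed, documented
function of ``(base_seed, replicate)`` that does not depend on the
configuration, so matched replicates of different configurations share their
initial randomness.

Final sent counts across the grid are analysed with a Gaussian
identity-link GLM (ordinary least squares) on the three dummy-coded factors,
with the random graph and the random agent as reference levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from msgspread.cascade import run_cascade
from msgspread.netgen import (
    NetworkSpec,
    assign_agents,
    generate_network,
    graph_metrics,
    pick_seed,
)
from msgspread.population import CONTENT_TYPES, make_message, make_population

__all__ = [
    "RESULTS_SCHEMA",
    "SchemaError",
    "SimulationConfig",
    "fit_glm",
    "read_results",
    "replicate_rng",
    "run_replications",
    "summarize",
    "sweep",
    "write_results",
]

#: Columns of a run-records table, in order.  Bump ``schema_version`` on change.
RESULTS_SCHEMA = (
    "schema_version",
    "config_id",
    "network_type",
    "n_agents",
    "agent_model",
    "content_type",
    "assignment",
    "replicate",
    "base_seed",
    "n_steps",
    "completed",
    "final_received",
    "final_noticed",
    "final_sent",
    "frac_received",
    "frac_noticed",
    "frac_sent",
    "frac_sent_among_received",
    "edges",
    "avg_clustering",
    "components",
)

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Raised when a results file does not match the expected schema."""


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the experimental grid."""

    network: NetworkSpec
    agent_model: str = "random"
    content_type: str = "both"
    assignment: str = "identity"
    replications: int = 1000
    base_seed: int = 0
    max_steps: Optional[int] = None
    attitude_dist: str = "uniform"
    seed_method: str = "degree"

    def __post_init__(self) -> None:
        if self.agent_model not in ("random", "personality"):
            raise ValueError(f"unknown agent_model {self.agent_model!r}")
        if self.content_type not in CONTENT_TYPES:
            raise ValueError(f"unknown content_type {self.content_type!r}")
        if self.assignment not in ("identity", "extraversion_rank"):
            raise ValueError(f"unknown assignment {self.assignment!r}")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")

    @property
    def config_id(self) -> str:
        return (
            f"{self.network.type}-n{self.network.n}-{self.agent_model}"
            f"-{self.content_type}-{self.assignment}"
        )


def replicate_rng(base_seed: int, replicate: int) -> np.random.Generator:
    """The random stream of one replicate: fixed function of (base_seed, r)."""
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(replicate,)))


def _run_one(
    config: SimulationConfig, r: int
) -> tuple[dict, list[int], list[int], list[int]]:
    rng = replicate_rng(config.base_seed, r)
    g = generate_network(config.network, rng)
    agents = make_population(
        g.number_of_nodes(),
        config.agent_model,
        rng,
        attitude_dist=config.attitude_dist,
    )
    placement = assign_agents(agents, g, config.assignment)
    seed_node = pick_seed(g, config.seed_method)
    traj = run_cascade(
        g, placement, make_message(config.content_type), seed_node, config.max_steps
    )
    metrics = graph_metrics(g)
    record = {
        "schema_version": SCHEMA_VERSION,
        "config_id": config.config_id,
        "network_type": config.network.type,
        "n_agents": traj.n_agents,
        "agent_model": config.agent_model,
        "content_type": config.content_type,
        "assignment": config.assignment,
        "replicate": r,
        "base_seed": config.base_seed,
        "n_steps": traj.n_steps,
        "completed": traj.completed,
        "final_received": traj.final_received,
        "final_noticed": traj.final_noticed,
        "final_sent": traj.final_forwarded,
        "frac_received": traj.frac_received,
        "frac_noticed": traj.frac_noticed,
        "frac_sent": traj.frac_forwarded,
        "frac_sent_among_received": traj.frac_forwarded_among_received,
        **metrics,
    }
    return record, traj.received, traj.noticed, traj.forwarded


def run_replications(
    config: SimulationConfig, collect_trajectories: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Run all replicates of one configuration.

    Returns the run-records table; with ``collect_trajectories=True`` also a
    long table with one row per step per replicate (cumulative counts).
    """
    records = []
    traj_rows = []
    for r in range(config.replications):
        try:
            record, received, noticed, forwarded = _run_one(config, r)
        except Exception as exc:
            raise RuntimeError(
                f"replicate {r} of {config.config_id} failed: {exc}"
            ) from exc
        records.append(record)
        if collect_trajectories:
            for k, (rec, noc, fwd) in enumerate(zip(received, noticed, forwarded)):
                traj_rows.append(
                    {
                        "config_id": config.config_id,
                        "replicate": r,
                        "step": k,
                        "received": rec,
                        "noticed": noc,
                        "forwarded": fwd,
                        "frac_received": rec / record["n_agents"],
                        "frac_forwarded": fwd / record["n_agents"],
                    }
                )
    runs = pd.DataFrame(records, columns=list(RESULTS_SCHEMA))
    if collect_trajectories:
        return runs, pd.DataFrame(traj_rows)
    return runs


def sweep(grid: Sequence[SimulationConfig]) -> pd.DataFrame:
    """Run every configuration in the grid and concatenate the records."""
    if not grid:
        raise ValueError("empty configuration grid")
    ids = [c.config_id for c in grid]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate configurations in grid: {sorted(dupes)}")
    return pd.concat(
        [run_replications(c) for c in grid], ignore_index=True
    )


def summarize(
    runs: pd.DataFrame, trajectories: Optional[pd.DataFrame] = None
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and standard error of the spread fractions per configuration.

    The standard error is ``sd / sqrt(replications)`` (ddof=1).  If a
    trajectory table is given, a per-step summary is returned as well.
    """
    if runs.empty:
        raise ValueError("no run records to summarize")

    def agg(group: pd.DataFrame) -> pd.Series:
        n = len(group)
        out = {"replications": n}
        for col in ("frac_sent", "frac_received", "frac_sent_among_received"):
            vals = group[col].to_numpy(dtype=float)
            out[f"mean_{col}"] = vals.mean()
            out[f"se_{col}"] = (
                vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            )
        return pd.Series(out)

    keys = ["config_id", "network_type", "n_agents", "agent_model", "content_type"]
    final = runs.groupby(keys, sort=True).apply(agg, include_groups=False).reset_index()
    if trajectories is None:
        return final

    def agg_step(group: pd.DataFrame) -> pd.Series:
        n = len(group)
        out = {}
        for col in ("frac_received", "frac_forwarded"):
            vals = group[col].to_numpy(dtype=float)
            out[f"mean_{col}"] = vals.mean()
            out[f"se_{col}"] = vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        return pd.Series(out)

    per_step = (
        trajectories.groupby(["config_id", "step"], sort=True)
        .apply(agg_step, include_groups=False)
        .reset_index()
    )
    return final, per_step


def fit_glm(runs: pd.DataFrame, family: str = "gaussian"):
    """Fit final sent count on agent, network, and content type.

    Gaussian identity GLM (equivalently OLS) with dummy coding; reference
    levels are the random graph and the random agent (content reference:
    ``weak``).  Returns a statsmodels results object whose summary carries
    estimates, standard errors, null/residual deviance, and AIC.
    """
    factors = {
        "agent_model": "random",
        "network_type": "random",
        "content_type": "weak",
    }
    for col, ref in factors.items():
        if col not in runs.columns:
            raise SchemaError(f"runs table lacks required column {col!r}")
        levels = runs[col].unique()
        if len(levels) < 2:
            raise ValueError(
                f"factor {col!r} needs >= 2 levels, found {sorted(map(str, levels))}"
            )
        if ref not in levels:
            factors[col] = sorted(levels)[0]
    formula = (
        "final_sent ~ "
        f"C(agent_model, Treatment('{factors['agent_model']}'))"
        f" + C(network_type, Treatment('{factors['network_type']}'))"
        f" + C(content_type, Treatment('{factors['content_type']}'))"
    )
    if family == "gaussian":
        # identity-link Gaussian GLM == OLS; the OLS path also handles a
        # degenerate constant response, where GLM's scale estimate vanishes
        return smf.ols(formula, data=runs).fit()
    if family == "poisson":
        return smf.glm(formula, data=runs, family=sm.families.Poisson()).fit()
    raise ValueError(f"unsupported GLM family {family!r}")


def glm_coefficient_table(result) -> pd.DataFrame:
    """Flatten a fitted GLM into a coefficient table with fit statistics."""
    table = pd.DataFrame(
        {
            "term": result.params.index,
            "estimate": result.params.to_numpy(),
            "std_error": result.bse.to_numpy(),
            "p_value": result.pvalues.to_numpy(),
        }
    )
    # on the OLS (gaussian) path the deviances are the centred total and
    # residual sums of squares, matching the Gaussian GLM definition
    table["null_deviance"] = (
        result.null_deviance if hasattr(result, "null_deviance") else result.centered_tss
    )
    table["residual_deviance"] = (
        result.deviance if hasattr(result, "deviance") else result.ssr
    )
    table["aic"] = result.aic
    return table


def write_results(runs: pd.DataFrame, path) -> None:
    """Write run records as CSV (lossless round trip via :func:`read_results`)."""
    missing = set(RESULTS_SCHEMA) - set(runs.columns)
    if missing:
        raise SchemaError(f"records are missing columns: {sorted(missing)}")
    runs.loc[:, list(RESULTS_SCHEMA)].to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    """Read a run-records CSV, validating the schema."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(RESULTS_SCHEMA) - set(df.columns)
    if missing:
        raise SchemaError(f"results file {path} is missing columns: {sorted(missing)}")
    versions = set(df["schema_version"].unique()) if len(df) else {SCHEMA_VERSION}
    if versions - {SCHEMA_VERSION}:
        raise SchemaError(f"unsupported schema versions {sorted(versions)}")
    return df
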