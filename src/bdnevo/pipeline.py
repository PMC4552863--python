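"""Parameter-space scans and reproducible end-to-end runs.

A scan walks a rectangular grid of (chemical, electrical) coupling pairs
and computes, per cell, the global synchronization and the information
flow capacity — on the fixed network (``static`` mode) or after growing
it (``evolve`` mode, recording mMIR).  Cells are independent and each is
seeded as ``base_seed + cell_index`` so partial scans are resumable and
cell results do not depend on execution order.  Results are long-format
tables (one row per cell) that survive partial failures.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import topology
from .dynamics import HRParams, SimConfig, SynapseParams, initial_state, simulate
from .evolution import evolve
from .lyapunov import two_largest_exponents
from .synchronization import order_parameter
from .topology import Connectome

logger = logging.getLogger(__name__)

__all__ = ["ScanResult", "GridSpec", "scan_parameter_space", "run_from_config",
           "ConfigError"]


class ConfigError(ValueError):
    """Configuration schema violation; the message names the field."""


@dataclass(frozen=True)
class GridSpec:
    """Inclusive rectangular grid over the two coupling strengths."""

    g_n_min: float
    g_n_max: float
    g_n_count: int
    g_l_min: float
    g_l_max: float
    g_l_count: int

    def __post_init__(self):
        if self.g_n_count < 1 or self.g_l_count < 1:
            raise ConfigError("grid counts must be >= 1")
        if self.g_n_max < self.g_n_min or self.g_l_max < self.g_l_min:
            raise ConfigError("grid ranges must be non-decreasing")

    def cells(self):
        gn = np.linspace(self.g_n_min, self.g_n_max, self.g_n_count)
        gl = np.linspace(self.g_l_min, self.g_l_max, self.g_l_count)
        return [(float(a), float(b)) for a in gn for b in gl]


@dataclass
class ScanResult:
    table: pd.DataFrame
    mode: str
    base_seed: int
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def _static_cell(net, hr, syn, cfg, seed):
    rng = np.random.default_rng(seed)
    state0 = initial_state(net, rng)
    est = two_largest_exponents(net, hr, syn, cfg, state0=state0)
    traj = simulate(net, hr, syn, cfg, state0=state0)
    _, rho, _ = order_parameter(traj.post_transient().phi)
    return rho, est.info_capacity, {}


def _evolve_cell(net, hr, syn, cfg, seed, candidate_cfg=None):
    evolved, trace = evolve(net, hr, syn, cfg.with_(seed=seed),
                            candidate_cfg=candidate_cfg)
    return trace.rho_history[-1], trace.mMIR, {
        "n_accepted": len(trace.accepted_links)}


def scan_parameter_space(net: Connectome, hr: HRParams, grid: GridSpec,
                         cfg: SimConfig, mode: str = "static",
                         base_seed: int = 0,
                         syn_template: SynapseParams = SynapseParams(),
                         candidate_cfg: SimConfig | None = None) -> ScanResult:
    """Per-cell synchronization and capacity over a coupling grid.

    ``static`` fills (rho, ic) on the fixed network; ``evolve`` runs the
    growth process per cell and fills (rho, mMIR).  A failing cell is
    recorded with its error message and does not abort the scan.
    """
    if mode not in ("static", "evolve"):
        raise ConfigError(f"mode must be 'static' or 'evolve', got {mode!r}")
    rows = []
    for idx, (g_n, g_l) in enumerate(grid.cells()):
        seed = base_seed + idx
        syn = SynapseParams(theta_syn=syn_template.theta_syn,
                            lambda_sig=syn_template.lambda_sig,
                            V_syn=syn_template.V_syn, g_n=g_n, g_l=g_l)
        row = {"g_n": g_n, "g_l": g_l, "seed": seed, "t_f": cfg.t_f,
               "rho": np.nan, "ic": np.nan, "status": "ok"}
        try:
            if mode == "static":
                rho, ic, extra = _static_cell(net, hr, syn, cfg, seed)
            else:
                rho, ic, extra = _evolve_cell(net, hr, syn, cfg, seed,
                                              candidate_cfg)
            row.update(rho=rho, ic=ic, **extra)
        except Exception as exc:  # noqa: BLE001 - cell isolation is the contract
            row["status"] = f"error: {exc}"
            logger.warning("cell %d (g_n=%.3g, g_l=%.3g) failed: %s",
                           idx, g_n, g_l, exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    return ScanResult(table, mode=mode, base_seed=base_seed,
                      meta={"t_f": cfg.t_f, "dt": cfg.dt, "t_t": cfg.t_t,
                            "n_neurons": net.n_neurons})


# ---------------------------------------------------------------------------
# Config-driven runs

_REQUIRED = {"mode", "out_dir", "base_seed"}


def _build_network(conf: dict) -> Connectome:
    kind = conf.get("topology", "ring_of_clusters")
    rng = np.random.default_rng(int(conf["base_seed"]))
    if kind == "ring_of_clusters":
        params = {}
        if conf.get("cluster_kind", "small_world") == "small_world":
            params = {"k_ring": int(conf.get("k_ring", 4)),
                      "p_rewire": float(conf.get("p_rewire", 0.1))}
        return topology.build_ring_of_clusters(
            int(conf.get("n_clusters", 6)), int(conf.get("n_per_cluster", 10)),
            cluster_kind=conf.get("cluster_kind", "small_world"),
            cluster_params=params, rng=rng)
    if kind == "file":
        if "topology_file" not in conf:
            raise ConfigError("topology_file: required when topology=file")
        return topology.load_connectome(
            conf["topology_file"], conf.get("topology_format", "edge_list"))
    raise ConfigError(f"topology: unknown kind {kind!r}")


def _sim_config(conf: dict) -> SimConfig:
    return SimConfig(dt=float(conf.get("dt", 0.01)),
                     t_f=float(conf.get("t_f", 2500.0)),
                     t_t=float(conf.get("t_t", 300.0)),
                     seed=int(conf["base_seed"]),
                     record_stride=int(conf.get("record_stride", 10)))


def _grid(conf: dict) -> GridSpec:
    missing = [k for k in ("g_n_min", "g_n_max", "g_n_count",
                           "g_l_min", "g_l_max", "g_l_count") if k not in conf]
    if missing:
        raise ConfigError(f"{missing[0]}: required for scan modes")
    return GridSpec(float(conf["g_n_min"]), float(conf["g_n_max"]),
                    int(conf["g_n_count"]), float(conf["g_l_min"]),
                    float(conf["g_l_max"]), int(conf["g_l_count"]))


def run_from_config(config_path: str) -> dict:
    """Execute the run a flat key-value config file describes and write
    its artifacts plus a provenance record to the output directory.

    Returns a mapping of artifact names to file paths.
    """
    import yaml

    with open(config_path) as fh:
        conf = yaml.safe_load(fh)
    if not isinstance(conf, dict):
        raise ConfigError("config: expected a flat key-value mapping")
    missing = _REQUIRED - conf.keys()
    if missing:
        raise ConfigError(f"{sorted(missing)[0]}: required key missing")

    out_dir = conf["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    mode = conf["mode"]
    net = _build_network(conf)
    cfg = _sim_config(conf)
    hr = HRParams()
    syn = SynapseParams(g_n=float(conf.get("g_n", 0.0)),
                        g_l=float(conf.get("g_l", 0.0)))
    artifacts = {}

    if mode in ("scan_static", "scan_evolve"):
        result = scan_parameter_space(
            net, hr, _grid(conf), cfg, mode=mode.removeprefix("scan_"),
            base_seed=int(conf["base_seed"]), syn_template=syn)
        path = os.path.join(out_dir, "scan.csv")
        result.to_csv(path)
        artifacts["scan"] = path
    elif mode == "simulate":
        traj = simulate(net, hr, syn, cfg)
        _, rho, _ = order_parameter(traj.post_transient().phi)
        path = os.path.join(out_dir, "summary.json")
        with open(path, "w") as fh:
            json.dump({"rho": rho, "n_neurons": net.n_neurons}, fh)
        artifacts["summary"] = path
    elif mode == "lyapunov":
        est = two_largest_exponents(net, hr, syn, cfg)
        path = os.path.join(out_dir, "lyapunov.csv")
        est.history_to_csv(path)
        artifacts["lyapunov"] = path
        path = os.path.join(out_dir, "summary.json")
        with open(path, "w") as fh:
            json.dump({"lambda1": est.lambda1, "lambda2": est.lambda2,
                       "ic": est.info_capacity}, fh)
        artifacts["summary"] = path
    elif mode == "evolve":
        evolved, trace = evolve(net, hr, syn, cfg)
        path = os.path.join(out_dir, "trace.json")
        trace.to_json(path)
        artifacts["trace"] = path
        path = os.path.join(out_dir, "evolved_chemical.edges")
        topology.save_connectome(evolved, path, layer="chemical")
        artifacts["evolved_chemical"] = path
    elif mode == "structure":
        from .graph_metrics import structure_report

        report = structure_report(net.combined,
                                  n_random=int(conf.get("n_random", 100)),
                                  rng=np.random.default_rng(int(conf["base_seed"])))
        path = os.path.join(out_dir, "structure.txt")
        report.to_file(path)
        artifacts["structure"] = path
    elif mode == "spectra":
        from .spectral import normalized_laplacian, spectral_density

        _, ev = normalized_laplacian(net.combined)
        density = spectral_density(ev)
        path = os.path.join(out_dir, "spectral_density.csv")
        density.to_csv(path)
        artifacts["spectral_density"] = path
    else:
        raise ConfigError(f"mode: unknown value {mode!r}")

    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("bdnevo")
    except PackageNotFoundError:
        pkg_version = "unknown"
    prov = os.path.join(out_dir, "provenance.json")
    with open(prov, "w") as fh:
        json.dump({"config": conf, "version": pkg_version,
                   "base_seed": int(conf["base_seed"])}, fh, indent=1)
    artifacts["provenance"] = prov
    return artifacts
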