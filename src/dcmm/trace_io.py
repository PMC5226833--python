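"""Trace file I/O, run configuration and end-to-end orchestration.

The analysis pipeline is: noise-filter each raw trace with the
Gaussian HMM, select the number of internal states and decode the
internal path with the variational double-chain model, decompose into
homogeneous components, then cluster the ensemble's kinetic arrows.
`run_pipeline` wires the stages together and writes diff-able CSV/JSON
artifacts plus a manifest keyed by config hash and seed.
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

from . import cluster as cluster_mod
from . import metrics
from .hmm_filter import compute_fret, fit_gaussian_hmm, viterbi_discretize
from .model_select import decompose, select_model
from .vbdcmm import Priors

__all__ = [
    "ObservableTrace",
    "RunConfig",
    "read_trace",
    "write_trace",
    "write_ground_truth",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class ObservableTrace:
    """A real-valued signal sampled at fixed dt."""

    values: np.ndarray
    dt: float
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt

    def __len__(self):
        return len(self.values)


@dataclass
class RunConfig:
    """All knobs of the end-to-end analysis."""

    dt: float = 0.1
    N: int = 2
    K_max: int = 5
    priors: Priors = field(default_factory=Priors)
    hmm_n_restarts: int = 3
    hmm_max_iter: int = 500
    vb_n_restarts: int = 10
    vb_max_iter: int = 1000
    vb_tol: float = 1e-6
    min_dwell: int = 10
    cluster_k_range: tuple = (2, 14, 2)
    min_cluster_size: int = 10
    cluster_n_init: int = 200
    cluster_metric: str = "sqeuclidean"
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if isinstance(self.priors, dict):
            self.priors = Priors(**self.priors)

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["cluster_k_range"] = list(d["cluster_k_range"])
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _uniform_dt(time, path):
    time = np.asarray(time, dtype=float)
    if len(time) < 2:
        raise ValueError(f"{path}: need at least two rows")
    diffs = np.diff(time)
    if np.any(diffs <= 0):
        row = int(np.flatnonzero(diffs <= 0)[0]) + 1
        raise ValueError(f"{path}: non-monotone time at row {row}")
    dt = diffs[0]
    bad = np.flatnonzero(~np.isclose(diffs, dt, rtol=1e-6, atol=1e-9))
    if bad.size:
        raise ValueError(f"{path}: non-uniform sampling at row {int(bad[0]) + 1}")
    return float(dt)


def read_trace(path, format=None) -> ObservableTrace:
    """Read a (time_s, fret) or (time_s, donor, acceptor) table.

    CSV, TSV or whitespace-delimited; a header is detected if the first
    row is non-numeric.  Three-column files are converted to FRET via
    E = I_A / (I_A + I_D).
    """
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0]
    has_header = any(
        not _is_number(tok) for tok in first.replace(",", " ").split()
    )
    df = pd.read_csv(
        path, sep=None, engine="python", header=0 if has_header else None
    )
    if df.shape[1] not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 columns, got {df.shape[1]}")
    if not df.map(np.isreal).all().all():
        raise ValueError(f"{path}: non-numeric cells")
    dt = _uniform_dt(df.iloc[:, 0].to_numpy(), path)
    if df.shape[1] == 2:
        values = df.iloc[:, 1].to_numpy(dtype=float)
    else:
        values = compute_fret(
            df.iloc[:, 1].to_numpy(dtype=float), df.iloc[:, 2].to_numpy(dtype=float)
        )
    return ObservableTrace(values=values, dt=dt, source=str(path))


def _is_number(tok):
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_trace(path, trace: ObservableTrace):
    pd.DataFrame({"time_s": trace.time, "fret": trace.values}).to_csv(
        path, index=False
    )


def write_ground_truth(path, gt, dt=None):
    """Ground truth as (time_s, o, x); x padded with 0 at the final frame."""
    dt = dt if dt is not None else (gt.config.dt if gt.config else 1.0)
    x_pad = np.concatenate([gt.x, [0]])
    pd.DataFrame(
        {"time_s": np.arange(len(gt.o)) * dt, "o": gt.o, "x": x_pad}
    ).to_csv(path, index=False)


def _analyze_trace(trace: ObservableTrace, config: RunConfig, seed, trace_id):
    hmm = fit_gaussian_hmm(
        trace.values,
        config.N,
        max_iter=config.hmm_max_iter,
        n_restarts=config.hmm_n_restarts,
        seed=seed,
    )
    o = viterbi_discretize(trace.values, hmm)
    scan = select_model(
        o,
        K_max=config.K_max,
        priors=config.priors,
        seed=seed,
        n_restarts=config.vb_n_restarts,
        max_iter=config.vb_max_iter,
        tol=config.vb_tol,
        N=config.N,
    )
    comps = decompose(
        o, scan.best_path, min_dwell=config.min_dwell, trace_id=trace_id, N=config.N
    )
    return hmm, o, scan, comps


def run_pipeline(config: RunConfig, traces, out_dir=None, ground_truth=None):
    """Run the full analysis over an ensemble.

    traces : mapping trace_id -> ObservableTrace (or list of file
    paths).  ground_truth : optional mapping trace_id -> GroundTruth
    for overlap scoring.  Per-trace failures are quarantined and the
    pipeline continues.  Returns the manifest dict; with `out_dir`,
    writes per-trace artifacts, the component table, the cluster scan
    and `manifest.json`.
    """
    if not isinstance(traces, dict):
        traces = {Path(p).stem: read_trace(p) for p in traces}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "traces": {},
        "failures": {},
    }
    all_comps = {}
    ids = sorted(traces)
    for trace_id, ss in zip(ids, root.spawn(len(ids))):
        seed = int(ss.generate_state(1)[0] % (2**31))
        try:
            hmm, o, scan, comps = _analyze_trace(
                traces[trace_id], config, seed, trace_id
            )
        except (ValueError, RuntimeError, FloatingPointError) as err:
            logger.warning("trace %s failed: %s", trace_id, err)
            manifest["failures"][trace_id] = str(err)
            continue
        all_comps[trace_id] = comps
        entry = {
            "K_star": scan.K_star,
            "K_obs": scan.K_obs[scan.K_star],
            "F": {str(k): v for k, v in scan.F.items()},
            "G": {str(k): v for k, v in scan.G.items()},
            "n_components": len(comps),
            "hmm_means": hmm.means.tolist(),
        }
        if ground_truth is not None and trace_id in ground_truth:
            gt = ground_truth[trace_id]
            best = scan.best
            try:
                perm = metrics.match_labels(
                    best.model.B,
                    gt.config.B,
                    x_est=scan.best_path,
                    x_true=gt.x,
                )
                entry["chi"] = metrics.overlap_chi(gt.x, scan.best_path, perm)
            except ValueError as err:
                entry["chi"] = None
                logger.warning("trace %s: scoring failed: %s", trace_id, err)
        manifest["traces"][trace_id] = entry
        if out_dir is not None:
            dt = traces[trace_id].dt
            x_pad = np.concatenate([scan.best_path, [0]])
            pd.DataFrame(
                {"time_s": np.arange(len(o)) * dt, "o": o, "x": x_pad}
            ).to_csv(out_dir / f"{trace_id}.decoded.csv", index=False)

    arrows = cluster_mod.build_arrows(all_comps)
    manifest["n_arrows"] = len(arrows)
    if len(arrows) >= 4:
        k_lo, k_hi, k_step = config.cluster_k_range
        k_values = [K for K in range(k_lo, min(k_hi, len(arrows)) + 1, k_step)]
        scan_c = cluster_mod.select_clusters(
            arrows,
            K_range=k_values,
            min_cluster_size=config.min_cluster_size,
            n_init=config.cluster_n_init,
            seed=config.seed,
            metric=config.cluster_metric,
        )
        manifest["cluster"] = {
            "K_star": scan_c.K_star,
            "D": {str(k): v for k, v in scan_c.D.items()},
            "D_c": {str(k): v for k, v in scan_c.D_c.items()},
            "eligible": {str(k): v for k, v in scan_c.eligible.items()},
        }
    else:
        scan_c = None
        manifest["cluster"] = None

    if out_dir is not None:
        rows = []
        for trace_id, comps in all_comps.items():
            for c in comps:
                row = {
                    "trace_id": trace_id,
                    "t_start": c.t_start,
                    "t_end": c.t_end,
                    "label": c.label,
                    "n_transitions": c.n_transitions,
                    "low_confidence": c.low_confidence,
                }
                N = c.rates.shape[0]
                for a in range(N):
                    for b in range(N):
                        if a != b:
                            row[f"k_{a + 1}to{b + 1}"] = c.rates[a, b]
                rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / "components.csv", index=False)
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=_json_default)
        )
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
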