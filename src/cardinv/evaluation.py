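"""Accuracy metrics and run manifests.

Metric vocabulary follows the validation literature of noninvasive
cardiac mapping: Pearson correlation per activation/repolarization
pattern, mean absolute and root-mean-square timing errors (after removal
of one global time shift, since simulation time zero is arbitrary
relative to reconstructed onset), and the pacing-site localization error
in millimetres.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import numpy as np

from .geometry import TriSurface
from .sources import SourceTiming

__all__ = [
    "AccuracyReport",
    "timing_metrics",
    "localization_error",
    "electrogram_correlation",
    "run_report",
    "verify_manifest",
]


@dataclass
class AccuracyReport:
    at_cc: float
    rt_cc: float
    at_mae_ms: float
    rt_mae_ms: float
    at_rmse_ms: float
    rt_rmse_ms: float
    shift_ms: float
    n_nodes: int
    n_missing: int
    localization_error_mm: float | None = None
    egm_median_cc: float | None = None

    def as_dict(self):
        return asdict(self)


def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    if den == 0:
        return 0.0
    return float(np.clip((a @ b) / den, -1.0, 1.0))


def timing_metrics(truth: SourceTiming, estimate: SourceTiming) -> AccuracyReport:
    """CC / MAE / RMSE of activation and repolarization times.

    Missing-flagged nodes are excluded pairwise.  One global best-fit
    (least-squares) time shift, pooled over AT and RT differences, is
    removed before the error norms and reported.
    """
    if truth.n_nodes != estimate.n_nodes:
        raise ValueError("timing registries differ in length")
    ok = ~(truth.missing() | estimate.missing())
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly non-missing nodes")
    dt_at = estimate.tau[ok] - truth.tau[ok]
    dt_rt = estimate.rho[ok] - truth.rho[ok]
    shift = float(np.concatenate([dt_at, dt_rt]).mean())
    at_err = dt_at - shift
    rt_err = dt_rt - shift
    return AccuracyReport(
        at_cc=_pearson(truth.tau[ok], estimate.tau[ok]),
        rt_cc=_pearson(truth.rho[ok], estimate.rho[ok]),
        at_mae_ms=float(np.abs(at_err).mean()),
        rt_mae_ms=float(np.abs(rt_err).mean()),
        at_rmse_ms=float(np.sqrt((at_err**2).mean())),
        rt_rmse_ms=float(np.sqrt((rt_err**2).mean())),
        shift_ms=shift,
        n_nodes=int(ok.sum()),
        n_missing=int((~ok).sum()),
    )


def localization_error(truth_focus: int, estimate: SourceTiming,
                       surface: TriSurface, metric: str = "euclidean") -> float:
    """Distance (mm) from the truth focus to the earliest estimated node.

    Ties in the estimated activation minimum resolve to the candidate
    closest to the truth focus.  ``metric`` is Euclidean by default;
    ``geodesic`` uses graph distances along the mesh.
    """
    tau = estimate.tau
    ok = np.isfinite(tau)
    if not ok.any():
        raise ValueError("estimated timing is missing everywhere")
    tmin = np.nanmin(tau)
    argmins = np.flatnonzero(ok & (tau == tmin))
    if metric == "euclidean":
        d = np.linalg.norm(surface.vertices[argmins]
                           - surface.vertices[truth_focus], axis=1)
        return float(d.min())
    if metric == "geodesic":
        from .geometry import fastest_route_times
        t = fastest_route_times(surface, {int(truth_focus): 0.0}, 1.0)
        return float(t[argmins].min())
    raise ValueError(f"unknown metric {metric!r}")


def electrogram_correlation(estimate_samples: np.ndarray,
                            truth_samples: np.ndarray) -> float:
    """Median per-node temporal Pearson correlation of electrograms."""
    if estimate_samples.shape != truth_samples.shape:
        raise ValueError("electrogram arrays differ in shape")
    ccs = [_pearson(e, t) for e, t in zip(estimate_samples, truth_samples)]
    return float(np.median(ccs))


# ---------------------------------------------------------------------------
# run manifests

def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_report(command: str, config, input_paths, seeds, metrics,
               out_path=None) -> dict:
    """JSON manifest of one run: config echo, input hashes, seeds, metrics."""
    import cardinv
    manifest = {
        "command": command,
        "config": _jsonable(config),
        "inputs": {str(p): _file_hash(p) for p in (input_paths or [])},
        "seeds": _jsonable(seeds),
        "versions": {
            "cardinv": cardinv.__version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        "metrics": _jsonable(metrics),
    }
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        with open(out_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def verify_manifest(manifest_path) -> dict:
    """Re-hash the manifest's inputs; report any mismatch."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    mismatches = {}
    for path, recorded in manifest.get("inputs", {}).items():
        if not Path(path).exists():
            mismatches[path] = "missing"
        else:
            now = _file_hash(path)
            if now != recorded:
                mismatches[path] = f"hash mismatch (was {recorded[:12]}, now {now[:12]})"
    return {"ok": not mismatches, "mismatches": mismatches}
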