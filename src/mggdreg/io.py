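"""File formats and evaluation reports.

Point clouds travel as delimited text (CSV/TSV/XYZ, one point per row,
'#' comments and a single header row tolerated) or ASCII PLY (through
trimesh).  Models and transforms serialize to JSON, configs and run
manifests to YAML.  Output is deterministic: fixed %.12g precision,
fixed column order, '\\n' newlines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .mggd import PointCloud
from .mixture import MixtureModel
from .registration import RigidTransform, registration_errors

__all__ = [
    "PointCloudFormatError",
    "read_point_cloud",
    "write_point_cloud",
    "save_model",
    "load_model",
    "save_transform",
    "load_transform",
    "match_components",
    "evaluate",
]

_DELIMS = {"csv": ",", "tsv": "\t", "xyz": None}  # None -> any whitespace


class PointCloudFormatError(ValueError):
    """Malformed point-cloud file; the message names the offending line."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    return suffix if suffix in ("csv", "tsv", "xyz", "ply") else "csv"


def read_point_cloud(path, fmt: str | None = None) -> PointCloud:
    """Read an N x d cloud; a trailing weights column is honored when the
    header announces it."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ply":
        return _read_ply(path)
    if fmt not in _DELIMS:
        raise PointCloudFormatError(f"unknown format {fmt!r}")
    delim = _DELIMS[fmt]
    rows: list[list[float]] = []
    has_weights = False
    ncol = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "weights" in line.lower():
                    has_weights = True
                continue
            cells = line.split(delim) if delim else line.split()
            try:
                values = [float(c) for c in cells]
            except ValueError:
                if not rows and ncol is None:
                    ncol = len(cells)  # tolerate one header row
                    continue
                raise PointCloudFormatError(
                    f"{path.name}:{lineno}: non-numeric cell in {line!r}"
                ) from None
            if ncol is None:
                ncol = len(values)
            elif len(values) != ncol:
                raise PointCloudFormatError(
                    f"{path.name}:{lineno}: expected {ncol} columns, got {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise PointCloudFormatError(f"{path.name}: no data rows")
    arr = np.array(rows, dtype=float)
    if has_weights:
        return PointCloud(points=arr[:, :-1], weights=arr[:, -1])
    return PointCloud(points=arr)


def _read_ply(path: Path) -> PointCloud:
    import trimesh

    obj = trimesh.load(str(path), process=False)
    pts = np.asarray(obj.vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise PointCloudFormatError(f"{path.name}: no vertices found")
    return PointCloud(points=pts)


def write_point_cloud(cloud: PointCloud, path, fmt: str | None = None) -> None:
    """Deterministic text output; weights become a trailing column that is
    announced in the header comment."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ply":
        _write_ply(cloud, path)
        return
    delim = _DELIMS.get(fmt)
    sep = delim if delim else " "
    data = cloud.points
    header = f"# mggdreg point cloud, {cloud.n} x {cloud.dim}"
    if cloud.weights is not None:
        data = np.column_stack([data, cloud.weights])
        header += ", trailing weights column"
    lines = [header]
    for row in data:
        lines.append(sep.join(f"{v:.12g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def _write_ply(cloud: PointCloud, path: Path) -> None:
    import trimesh

    pts = cloud.points
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(pts.shape[0])])
    data = trimesh.points.PointCloud(pts).export(file_type="ply", encoding="ascii")
    path.write_bytes(data if isinstance(data, bytes) else data.encode())


# ---------------------------------------------------------------------------
# model / transform JSON


def save_model(model: MixtureModel, path, fit_report: dict | None = None) -> None:
    doc = model.to_dict()
    if fit_report is not None:
        doc["fit_report"] = fit_report
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_model(path) -> MixtureModel:
    return MixtureModel.from_dict(json.loads(Path(path).read_text()))


def save_transform(tf: RigidTransform, path, extra: dict | None = None) -> None:
    doc = tf.to_dict()
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_transform(path) -> RigidTransform:
    return RigidTransform.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# evaluation


def match_components(
    est_means: np.ndarray, true_means: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian assignment of estimated to true components on mean
    distance; permutation-invariant."""
    cost = np.linalg.norm(
        est_means[:, None, :] - true_means[None, :, :], axis=-1
    )
    rows, cols = linear_sum_assignment(cost)
    return rows, cols


def evaluate(
    fitted_model: MixtureModel | None = None,
    true_means: np.ndarray | None = None,
    true_pis: np.ndarray | None = None,
    est_transform: RigidTransform | None = None,
    true_transform: RigidTransform | None = None,
) -> dict:
    """Metrics report: registration errors, parameter-recovery deltas
    after optimal component matching, selected K and a local-optimum flag
    (rotation error beyond 90% of pi)."""
    report: dict = {}
    if fitted_model is not None and true_means is not None:
        true_means = np.atleast_2d(np.asarray(true_means, dtype=float))
        est_means = np.vstack([c.mean for c in fitted_model.components])
        rows, cols = match_components(est_means, true_means)
        deltas = np.linalg.norm(est_means[rows] - true_means[cols], axis=1)
        report["k_selected"] = fitted_model.k
        report["mean_errors"] = {
            int(c): float(d) for c, d in zip(cols, deltas)
        }
        if true_pis is not None:
            pis = np.asarray(true_pis, dtype=float).ravel()
            report["pi_errors"] = {
                int(c): float(abs(fitted_model.weights_mix[r] - pis[c]))
                for r, c in zip(rows, cols)
            }
    if est_transform is not None and true_transform is not None:
        err = registration_errors(est_transform, true_transform)
        report["rotation_error_rel"] = err.rot_err
        report["translation_error_rel"] = err.trans_err
        report["rotation_error_abs"] = err.rot_abs
        report["translation_error_abs"] = err.trans_abs
        report["relative_errors_valid"] = err.relative
        report["local_optimum"] = bool(err.rot_abs > 0.9 * np.pi)
    return report
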