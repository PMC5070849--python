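"""End-to-end orchestration: load, project, estimate, extract, export.

The pipeline is a pure function of (input files, configuration, seed):
every SVD sign is pinned and every tolerance is recorded in the emitted
manifest, so reruns with the same configuration are bitwise identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_data, metagene, patterns, statespace
from .errors import SSXError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run."""

    internal_path: str
    external_path: str
    out_dir: str
    name: str = "dataset"
    log2: bool = False
    center: bool = False
    m1: int | None = None
    m2: int | None = None
    variance_target: float = 0.98
    external_lags: int = 1
    pinv_rtol: float = statespace.PINV_RTOL
    unit_tol: float = patterns.UNIT_TOL
    real_tol: float = patterns.REAL_TOL
    seed: int = 0

    def validate(self) -> "RunConfig":
        for key in ("pinv_rtol", "unit_tol", "real_tol"):
            if getattr(self, key) <= 0:
                raise ValidationError(f"{key} must be positive")
        if not 0 < self.variance_target <= 1:
            raise ValidationError("variance_target must be in (0, 1]")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` text file."""
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        kwargs = {}
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            if "=" not in ln:
                raise ValidationError(f"config line without '=': {ln!r}")
            key, _, val = ln.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ValidationError(f"unknown config key {key!r}")
            kwargs[key] = _coerce(key, val)
        return cls(**kwargs).validate()


def _coerce(key: str, val: str):
    if val.lower() in ("none", ""):
        return None
    if key in ("log2", "center"):
        return val.lower() in ("1", "true", "yes", "on")
    if key in ("m1", "m2", "external_lags", "seed"):
        return int(val)
    if key in ("variance_target", "pinv_rtol", "unit_tol", "real_tol"):
        return float(val)
    return val


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", float_format="%.12g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the five pipeline stages and write a run manifest.

    Stages: (A) load and validate the two expression matrices; (B) SVD
    metagene projection of each group; (C) least-squares estimation of
    the effective state-space model; (D) trajectory decomposition and
    dynamic-pattern extraction; (E) gene-level coefficient tables.
    Returns the manifest dict (also written to ``manifest.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def _stage(stage_name):
        return _StageTimer(stage_name, stages)

    with _stage("load"):
        ids_x, mat_x, labels = io_data.read_expression_matrix(
            config.internal_path
        )
        ids_u, mat_u, labels_u = io_data.read_expression_matrix(
            config.external_path
        )
        ds = io_data.assemble_dataset(
            (ids_x, mat_x), (ids_u, mat_u), labels, config.name,
            log2=config.log2, center=config.center,
        )

    with _stage("metagenes"):
        t = ds.n_timepoints
        if config.m1 is not None:
            m1 = config.m1
        else:
            m1, _ = metagene.choose_dimension(
                ds.internal_matrix, config.variance_target
            )
        if config.m2 is not None:
            m2 = config.m2
        else:
            m2, _ = metagene.choose_dimension(
                ds.external_matrix, config.variance_target, partner_M=m1
            )
        basis_x = metagene.fit_metagenes(ds.internal_matrix, m1, "internal")
        basis_u = metagene.fit_metagenes(ds.external_matrix, m2, "external")

    with _stage("estimate"):
        if m1 + m2 > t - 1:
            raise SSXError(
                f"stage estimate: M1+M2={m1 + m2} exceeds T-1={t - 1}"
            )
        model = statespace.estimate_model(basis_x.scores, basis_u.scores)

    with _stage("patterns"):
        X1 = basis_x.scores[:, 0]
        decomp = statespace.decompose(
            model, X1, basis_u.scores, external_lags=config.external_lags
        )
        ipdps = patterns.extract_ipdps(model.A_tilde, X1, t)
        epdps = patterns.extract_epdps(model.B_tilde, basis_u.scores)

    with _stage("coefficients"):
        coeffs_i = patterns.gene_coefficients_ipdp(basis_x, ipdps)
        coeffs_i.index = ds.internal_ids
        coeffs_e = patterns.gene_coefficients_epdp(basis_x, model.B_tilde)
        coeffs_e.index = ds.internal_ids

    # ---- artifacts -------------------------------------------------
    io_data.write_expression_matrix(
        out / "metagene_scores_internal.tsv",
        [f"mx{i + 1}" for i in range(m1)], basis_x.scores,
    )
    io_data.write_expression_matrix(
        out / "metagene_scores_external.tsv",
        [f"mu{i + 1}" for i in range(m2)], basis_u.scores,
    )
    io_data.write_expression_matrix(
        out / "W_internal.tsv", ds.internal_ids, basis_x.W,
        [f"mx{i + 1}" for i in range(m1)],
    )
    io_data.write_expression_matrix(
        out / "W_external.tsv", ds.external_ids, basis_u.W,
        [f"mu{i + 1}" for i in range(m2)],
    )
    np.savetxt(out / "A_tilde.tsv", model.A_tilde, delimiter="\t")
    np.savetxt(out / "B_tilde.tsv", model.B_tilde, delimiter="\t")
    for tag, arr in (
        ("internal", decomp.internal),
        ("external", decomp.external),
        ("interaction", decomp.interaction),
    ):
        np.savetxt(out / f"component_{tag}.tsv", arr, delimiter="\t")
    pat_records = []
    for p in ipdps + epdps:
        pat_records.append(
            {
                "kind": p.kind,
                "index": p.index,
                "eigenvalue": (
                    [p.eigenvalue.real, p.eigenvalue.imag]
                    if p.eigenvalue is not None else None
                ),
                "merged_conjugate": p.is_merged_conjugate,
                "class": p.class_label,
                "period": p.period,
                "trajectory": p.trajectory.tolist(),
                "trajectory_unit": p.trajectory_unit.tolist(),
            }
        )
    (out / "patterns.json").write_text(
        json.dumps(pat_records, indent=1, sort_keys=True)
    )
    _write_tsv(out / "gene_coefficients_ipdp.tsv", coeffs_i)
    _write_tsv(out / "gene_coefficients_epdp.tsv", coeffs_e)

    artifact_names = sorted(
        p.name for p in out.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    cfg = asdict(config)
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "tolerances": {
            "pinv_rtol": config.pinv_rtol,
            "unit_tol": config.unit_tol,
            "real_tol": config.real_tol,
        },
        "dataset": {
            "name": ds.name, "N1": ds.n_internal, "N2": ds.n_external,
            "T": ds.n_timepoints,
        },
        "dimensions": {"M1": m1, "M2": m2},
        "model": {
            "residual_norm": model.residual_norm,
            "rank_upsilon": model.rank_upsilon,
            "decomposition_total_check": decomp.total_check,
            "explained_fraction_internal": basis_x.explained_fraction,
            "explained_fraction_external": basis_u.explained_fraction,
        },
        "stages": stages,
        "artifacts": {n: _sha256(out / n) for n in artifact_names},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


class _StageTimer:
    """Records stage completion; re-raises errors tagged with the stage."""

    def __init__(self, name: str, log: list[dict]):
        self.name = name
        self.log = log

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s started", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise SSXError(f"stage {self.name!r} failed: {exc}") from exc
        # timings go to the log, not the manifest: the manifest must be
        # bitwise reproducible across reruns
        self.log.append({"stage": self.name, "status": "completed"})
        logger.info(
            "stage %s completed in %.3fs",
            self.name, time.perf_counter() - self.t0,
        )
        return False
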