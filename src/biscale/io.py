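"""Format readers/writers, run manifests, config and logging.

Conventions stated in every sidecar: coordinates are 0-based pixel units
with x = column and y = row; intervals are half-open.  Expression tables
are dense TSV with genes as rows and a header of sample ids, or MTX
triplets with genes.tsv / barcodes.tsv companions.  Embeddings are .npy
arrays with a JSON sidecar recording slide id, dimensionality, ordering
and encoder name.  Every artifact directory carries a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import csc_matrix

from . import __version__
from .expr_prep import ExpressionMatrix, make_pseudobulk
from .synthetic_data import BulkSample, Cohort, SpotSample, SynthConfig

COORD_CONVENTION = {"origin": "top-left", "zero_based": True,
                    "x": "column", "y": "row", "intervals": "half-open"}

log = logging.getLogger("biscale")


def setup_logging(level: str = "INFO") -> None:
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("biscale")
    root.handlers[:] = [h]
    root.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index=True, index_label="gene_id",
                        float_format="%.10g")


def read_expression_tsv(path, state: str = "raw_counts") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.to_numpy(float), [str(g) for g in df.index],
                            [str(s) for s in df.columns], state)


def read_table_tsv(path) -> pd.DataFrame:
    """A genes x samples table with no expression invariants enforced
    (model predictions may dip below zero in log space)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_expression_mtx(m: ExpressionMatrix, prefix) -> None:
    """MTX triplet: <prefix>.mtx plus <prefix>.genes.tsv / .barcodes.tsv."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csc_matrix(m.values))
    prefix.with_suffix(".genes.tsv").write_text("\n".join(m.gene_ids) + "\n")
    prefix.with_suffix(".barcodes.tsv").write_text("\n".join(m.sample_ids) + "\n")


def read_expression_mtx(prefix, state: str = "raw_counts") -> ExpressionMatrix:
    prefix = Path(prefix)
    values = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense(), dtype=float)
    genes = prefix.with_suffix(".genes.tsv").read_text().splitlines()
    barcodes = prefix.with_suffix(".barcodes.tsv").read_text().splitlines()
    return ExpressionMatrix(values, genes, barcodes, state)


# ---------------------------------------------------------------------------
# Spot positions (Visium tissue-positions convention) and embeddings
# ---------------------------------------------------------------------------

POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                    "pixel_row", "pixel_col"]


def write_positions_tsv(path, barcodes, pixel_xy: np.ndarray,
                        array_rc: np.ndarray | None = None) -> None:
    pixel_xy = np.asarray(pixel_xy, int)
    n = len(barcodes)
    if array_rc is None:
        array_rc = np.zeros((n, 2), dtype=int)
    pd.DataFrame({
        "barcode": list(barcodes),
        "in_tissue": np.ones(n, dtype=int),
        "array_row": array_rc[:, 0],
        "array_col": array_rc[:, 1],
        "pixel_row": pixel_xy[:, 1],   # y
        "pixel_col": pixel_xy[:, 0],   # x
    }).to_csv(path, sep="\t", index=False)


def read_positions_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"positions table missing column(s) {missing}")
    return df


def write_embeddings(prefix, embeddings: np.ndarray, coords: np.ndarray,
                     slide_id: str, ordering: str = "x_major",
                     encoder: str = "synthetic", patch_size: int = 256) -> None:
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), np.asarray(embeddings, float))
    sidecar = {
        "slide_id": slide_id, "d": int(np.asarray(embeddings).shape[1]),
        "n": int(np.asarray(embeddings).shape[0]), "ordering": ordering,
        "encoder": encoder, "patch_size": patch_size,
        "coords": np.asarray(coords, int).tolist(),
        "coord_convention": COORD_CONVENTION,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_embeddings(prefix) -> tuple[np.ndarray, np.ndarray, dict]:
    prefix = Path(prefix)
    emb = np.load(prefix.with_suffix(".npy"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    coords = np.asarray(sidecar["coords"], int)
    return emb, coords, sidecar


# ---------------------------------------------------------------------------
# Synthetic cohort directory layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> None:
    """Write a synthetic cohort in the pipeline's standard on-disk formats.

    Layout: bulk_targets.tsv and spot_global_targets.tsv (genes x slides,
    log2 scale), embeddings/<slide>.npy+.json, per-slide spot target TSVs,
    raw count tables when counts were generated, and truth.npz with the
    generative maps.
    """
    outdir = Path(outdir)
    (outdir / "embeddings").mkdir(parents=True, exist_ok=True)
    (outdir / "spots").mkdir(exist_ok=True)
    genes = cohort.truth.gene_ids

    bulk_targets = pd.DataFrame(
        {s.slide_id: s.z_global for s in cohort.bulk}, index=genes)
    bulk_targets.to_csv(outdir / "bulk_targets.tsv", sep="\t",
                        index_label="gene_id", float_format="%.12g")
    pd.DataFrame({s.slide_id: s.patient_id for s in cohort.bulk}, index=["patient_id"]) \
        .T.to_csv(outdir / "bulk_patients.tsv", sep="\t", index_label="slide_id")

    spot_globals = pd.DataFrame(
        {s.slide_id: s.z_global for s in cohort.spots}, index=genes)
    spot_globals.to_csv(outdir / "spot_global_targets.tsv", sep="\t",
                        index_label="gene_id", float_format="%.12g")
    pd.DataFrame({s.slide_id: s.patient_id for s in cohort.spots}, index=["patient_id"]) \
        .T.to_csv(outdir / "spot_patients.tsv", sep="\t", index_label="slide_id")

    for s in cohort.bulk:
        write_embeddings(outdir / "embeddings" / s.slide_id, s.embeddings,
                         s.coords, s.slide_id)
    if any(s.counts is not None for s in cohort.bulk):
        counts = pd.DataFrame({s.slide_id: s.counts for s in cohort.bulk}, index=genes)
        counts.to_csv(outdir / "bulk_counts.tsv", sep="\t",
                      index_label="gene_id", float_format="%.12g")

    for s in cohort.spots:
        write_embeddings(outdir / "embeddings" / s.slide_id, s.embeddings,
                         s.coords, s.slide_id)
        barcodes = [f"{s.slide_id}-spot{i:04d}" for i in range(len(s.coords))]
        write_positions_tsv(outdir / "spots" / f"{s.slide_id}.positions.tsv",
                            barcodes, s.coords)
        pd.DataFrame(s.z_local.T, index=genes, columns=barcodes).to_csv(
            outdir / "spots" / f"{s.slide_id}.targets.tsv", sep="\t",
            index_label="gene_id", float_format="%.12g")
        if s.counts is not None:
            em = ExpressionMatrix(s.counts, list(genes), barcodes, "raw_counts")
            write_expression_mtx(em, outdir / "spots" / f"{s.slide_id}.counts")

    t = cohort.truth
    np.savez(outdir / "truth.npz",
             embed_weights=t.embed_weights, embed_bias=t.embed_bias,
             expr_weights=t.expr_weights, expr_bias=t.expr_bias,
             gene_ids=np.array(t.gene_ids),
             **{f"bulk_lat_{k}": v for k, v in t.bulk_latents.items()},
             **{f"spot_lat_{k}": v for k, v in t.spot_latents.items()})
    if cohort.config is not None:
        (outdir / "synth_config.json").write_text(
            json.dumps(asdict(cohort.config), sort_keys=True))


def read_cohort(indir) -> tuple[list[BulkSample], list[SpotSample], list[str]]:
    """Reassemble model-ready samples from a cohort directory."""
    indir = Path(indir)
    bulk_targets = pd.read_csv(indir / "bulk_targets.tsv", sep="\t", index_col=0)
    genes = [str(g) for g in bulk_targets.index]
    bulk_pat = pd.read_csv(indir / "bulk_patients.tsv", sep="\t", index_col=0)[
        "patient_id"].to_dict()
    spot_globals = pd.read_csv(indir / "spot_global_targets.tsv", sep="\t", index_col=0)
    spot_pat = pd.read_csv(indir / "spot_patients.tsv", sep="\t", index_col=0)[
        "patient_id"].to_dict()

    bulk = []
    for sid in bulk_targets.columns:
        emb, coords, _ = read_embeddings(indir / "embeddings" / sid)
        bulk.append(BulkSample(sid, str(bulk_pat[sid]), emb, coords, None,
                               bulk_targets[sid].to_numpy(float)))
    spots = []
    for sid in spot_globals.columns:
        emb, coords, _ = read_embeddings(indir / "embeddings" / sid)
        z_local = pd.read_csv(indir / "spots" / f"{sid}.targets.tsv",
                              sep="\t", index_col=0).to_numpy(float).T
        counts_prefix = indir / "spots" / f"{sid}.counts"
        counts = None
        if counts_prefix.with_suffix(".mtx").exists():
            counts = read_expression_mtx(counts_prefix).values
        spots.append(SpotSample(sid, str(spot_pat[sid]), emb, coords, counts,
                                z_local, spot_globals[sid].to_numpy(float)))
    return bulk, spots, genes


def pseudobulk_check(sample: SpotSample, genes: list[str]) -> np.ndarray:
    """Recompute the pseudo-bulk CPM vector from a sample's stored counts."""
    from .synthetic_data import spot_counts_matrix
    return make_pseudobulk(spot_counts_matrix(sample, genes))


# ---------------------------------------------------------------------------
# Config and run manifests
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a YAML mapping")
    return cfg


def synth_config_from_dict(cfg: dict, seed: int | None = None) -> SynthConfig:
    fields = {k: v for k, v in cfg.items() if k in SynthConfig.__dataclass_fields__}
    sc = SynthConfig(**fields)
    if seed is not None:
        sc.seed = seed
    return sc


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, command: str, seed: int | None,
                   config: dict | None = None, inputs: list | None = None) -> Path:
    """Write run metadata next to the artifacts it describes."""
    cfg_json = json.dumps(config or {}, sort_keys=True)
    manifest = {
        "command": command,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "inputs": {str(p): sha256_file(p) for p in (inputs or []) if Path(p).is_file()},
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
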