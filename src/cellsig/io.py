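"""Readers and writers: 10x-style MTX triplet directories, GMT gene sets, TSVs.

The MTX dialect is the droplet-deposit convention: ``matrix.mtx`` holds a
genes-as-rows sparse integer matrix, ``features.tsv`` one gene per line,
``barcodes.tsv`` one cell per line, optionally accompanied by
``metadata.tsv`` with per-cell ``condition`` and ``cluster`` columns. Plain or
gzip-compressed files are read transparently. Orientation is auto-detected
against the feature/barcode counts and normalized to cells-by-genes in the
returned AnnData.

GMT convention: tab-separated ``name, description, member...`` lines; a line
named ``NAME_down`` is merged with the line ``NAME`` into one bidirectional
signature.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .exceptions import EmptyResultError, FormatError
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

_MTX_NAMES = ("matrix.mtx",)
_FEATURE_NAMES = ("features.tsv", "genes.tsv")
_BARCODE_NAMES = ("barcodes.tsv",)
METADATA_NAME = "metadata.tsv"


def _find(directory: Path, names) -> Path:
    for name in names:
        for cand in (directory / name, directory / (name + ".gz")):
            if cand.exists():
                return cand
    raise FormatError(f"none of {names} found in {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_lines(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def dedupe_names(names) -> list[str]:
    """Make names unique by suffixing repeats with -1, -2, ..."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            new = f"{name}-{seen[name]}"
            logger.warning("duplicated name '%s' renamed to '%s'", name, new)
            out.append(new)
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_10x_mtx(directory) -> ad.AnnData:
    """Read an MTX triplet directory into a cells-by-genes AnnData.

    Counts are stored as integers; duplicated gene IDs are suffixed; the
    matrix orientation is detected from the feature/barcode counts. When a
    ``metadata.tsv`` is present its ``condition``/``cluster`` columns are
    attached to ``.obs`` by barcode.
    """
    directory = Path(directory)
    mtx_path = _find(directory, _MTX_NAMES)
    features = [line.split("\t")[0] for line in _read_lines(_find(directory, _FEATURE_NAMES))]
    barcodes = [line.split("\t")[0] for line in _read_lines(_find(directory, _BARCODE_NAMES))]

    if mtx_path.suffix == ".gz":
        with gzip.open(mtx_path, "rb") as fh:
            mat = spio.mmread(fh)
    else:
        mat = spio.mmread(mtx_path)
    mat = sparse.csr_matrix(mat)

    n_feat, n_bc = len(features), len(barcodes)
    if mat.shape == (n_feat, n_bc):
        mat = mat.T.tocsr()  # stored genes-as-rows; normalize to cells x genes
    elif mat.shape == (n_bc, n_feat):
        pass
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {n_feat} features x "
            f"{n_bc} barcodes nor its transpose"
        )
    adata = ad.AnnData(
        X=mat.astype(np.int32),
        obs=pd.DataFrame(index=dedupe_names(barcodes)),
        var=pd.DataFrame(index=dedupe_names(features)),
    )
    meta_path = None
    for cand in (directory / METADATA_NAME, directory / (METADATA_NAME + ".gz")):
        if cand.exists():
            meta_path = cand
    if meta_path is not None:
        meta = read_metadata(meta_path)
        meta = meta.reindex(adata.obs_names)
        for col in meta.columns:
            adata.obs[col] = meta[col].values
    return adata


def read_metadata(path) -> pd.DataFrame:
    """Cell metadata TSV with a ``barcode`` column as index."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "barcode" not in meta.columns:
        raise FormatError(f"{path} lacks a 'barcode' column")
    return meta.set_index("barcode")


def write_10x(adata: ad.AnnData, directory) -> None:
    """Write an AnnData's raw counts as a genes-as-rows MTX triplet + metadata.

    Round-trips losslessly through :func:`read_10x_mtx`.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise EmptyResultError("refusing to write an empty matrix")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    spio.mmwrite(str(directory / "matrix.mtx"), X.T.tocoo(), field="integer")
    (directory / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in adata.var_names)
    )
    (directory / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in adata.obs_names)
    )
    meta = pd.DataFrame(index=adata.obs_names.rename("barcode"))
    for col in ("condition", "cluster"):
        if col in adata.obs:
            meta[col] = np.asarray(adata.obs[col]).astype(str)
    meta.to_csv(directory / METADATA_NAME, sep="\t")
    logger.info("wrote %d genes x %d cells to %s", adata.n_vars, adata.n_obs,
                directory)


DOWN_SUFFIX = "_down"


def read_gmt(path) -> list[GeneSignature]:
    """Parse a GMT file into signatures, merging ``NAME``/``NAME_down`` pairs."""
    path = Path(path)
    lines = _read_lines(path) if path.exists() else None
    if lines is None:
        raise FormatError(f"GMT file not found: {path}")
    if not lines:
        logger.warning("empty GMT file: %s", path)
        return []
    order: list[str] = []
    up: dict[str, tuple[str, ...]] = {}
    down: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                f"(name, description, members...)"
            )
        name, members = fields[0], tuple(g for g in fields[2:] if g)
        if name.endswith(DOWN_SUFFIX):
            base = name[: -len(DOWN_SUFFIX)]
            down[base] = down.get(base, ()) + members
            if base not in order and base not in up:
                order.append(base)
        else:
            up[name] = up.get(name, ()) + members
            if name not in order:
                order.append(name)
    sigs = []
    for name in order:
        sigs.append(GeneSignature(name, up.get(name, ()), down.get(name, ())))
    return sigs


def write_gmt(signatures, path, description: str = "cellsig") -> None:
    """Write signatures as GMT, emitting a ``NAME_down`` line when needed."""
    with open(path, "w") as fh:
        for sig in signatures:
            if sig.up_genes:
                fh.write("\t".join([sig.name, description, *sig.up_genes]) + "\n")
            if sig.down_genes:
                fh.write("\t".join([sig.name + DOWN_SUFFIX, description,
                                    *sig.down_genes]) + "\n")


def write_scores_tsv(scores_by_sig, path) -> None:
    """Long-format score table: (barcode, signature, method, score)."""
    frames = []
    for sig_scores in scores_by_sig:
        for method, s in sig_scores.items():
            frames.append(pd.DataFrame({
                "barcode": s.barcodes,
                "signature": s.signature_name,
                "method": method,
                "score": s.score,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_cerno_tsv(result, path, q_threshold: float = 0.05) -> None:
    """Per-cell CERNO table: (barcode, condition, F, p, q, enriched_flag)."""
    table = result.table.copy()
    if "q" in table.columns:
        table["enriched"] = table["q"] < q_threshold
    table.to_csv(path, sep="\t")
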