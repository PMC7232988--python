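"""Readers and writers for dense maps, well tables and annotation catalogues.

Volumetric maps are NIfTI-1 (via nibabel), surface scalars are GIFTI func
or FreeSurfer curv files, wells are plain CSV with header
``gene_id,x_mm,y_mm,z_mm,value`` and annotations are two-column TSV
(term_id, gene_id) with an optional term-metadata sidecar.  Masking is
applied once, at load: downstream stages only ever see masked sites.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from coexmap.errors import IOFormatError
from coexmap.geometry import (
    AnnotationCatalogue,
    DomainGeometry,
    SampleSet,
    TargetMap,
)

WELL_COLUMNS = ["gene_id", "x_mm", "y_mm", "z_mm", "value"]


# ---------------------------------------------------------------------------
# dense maps
# ---------------------------------------------------------------------------

def geometry_from_nifti(path) -> DomainGeometry:
    """Build a volumetric geometry from a NIfTI file.

    Every finite, non-NaN voxel becomes a site; coordinates are world-space
    mm (affine applied), so kriging distances are metric.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise IOFormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    idx = np.array(np.nonzero(np.ones(data.shape, dtype=bool))).T
    coords = nib.affines.apply_affine(img.affine, idx)
    mask = np.isfinite(data[tuple(idx.T)])
    return DomainGeometry(
        coords=coords,
        space="volume",
        mask=mask,
        affine=np.asarray(img.affine),
        vol_shape=data.shape,
        voxel_indices=idx,
    )


def read_dense_map(path, geometry: DomainGeometry, name: str | None = None) -> TargetMap:
    """Read a dense scalar map aligned to ``geometry``.

    Dispatches on extension: ``.nii``/``.nii.gz`` (volume), ``.gii``
    (GIFTI func) or anything else as FreeSurfer curv.  NaN sites are
    excluded from the returned map's mask.
    """
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        if geometry.voxel_indices is not None:
            if data.shape != geometry.vol_shape:
                raise IOFormatError(
                    f"{path}: volume shape {data.shape} does not match geometry "
                    f"shape {geometry.vol_shape}"
                )
            values = data[tuple(geometry.voxel_indices.T)]
        else:
            values = data.ravel()
    elif suffixes.endswith(".gii"):
        img = nib.load(str(path))
        values = np.asarray(img.darrays[0].data, dtype=float)
    else:
        values = np.asarray(nib.freesurfer.read_morph_data(str(path)), dtype=float)
    if len(values) != geometry.n_sites:
        raise IOFormatError(
            f"{path}: found {len(values)} values, geometry expects "
            f"{geometry.n_sites} sites"
        )
    good = np.isfinite(values)
    geom = geometry.with_mask(good) if not good.all() else geometry
    values = values.astype(float)
    values[~good] = np.nan
    return TargetMap(geometry=geom, values=values, name=name or path.stem)


def write_dense_map(path, target: TargetMap) -> None:
    """Write a map as NIfTI (volume geometries) or GIFTI/curv (surface)."""
    path = Path(path)
    geom = target.geometry
    values = np.where(geom.mask, target.values, np.nan)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        if geom.vol_shape is None or geom.voxel_indices is None:
            raise IOFormatError("geometry carries no volumetric layout for NIfTI output")
        vol = np.full(geom.vol_shape, np.nan)
        vol[tuple(geom.voxel_indices.T)] = values
        affine = geom.affine if geom.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), str(path))
    elif suffixes.endswith(".gii"):
        darray = nib.gifti.GiftiDataArray(
            values.astype(np.float32), intent="NIFTI_INTENT_NONE"
        )
        nib.save(nib.gifti.GiftiImage(darrays=[darray]), str(path))
    else:
        nib.freesurfer.write_morph_data(str(path), values)


# ---------------------------------------------------------------------------
# well tables
# ---------------------------------------------------------------------------

def read_samples(path) -> list[SampleSet]:
    """Read per-gene well samples from CSV.

    One :class:`SampleSet` per distinct gene_id, in first-appearance order.
    Duplicate coordinates within a gene are averaged with a warning; genes
    with fewer than 3 wells are loaded but flagged (``fittable`` False)
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty well table", stacklevel=2)
        return []
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise IOFormatError(f"{path}: missing required columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty well table", stacklevel=2)
        return []
    out = []
    for gene_id, grp in df.groupby("gene_id", sort=False):
        ss = SampleSet(
            gene_id=str(gene_id),
            coords=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
            values=grp["value"].to_numpy(float),
        ).dedupe()
        if not ss.fittable:
            warnings.warn(
                f"gene {gene_id}: only {ss.n_wells} wells (<3); flagged unfittable",
                stacklevel=2,
            )
        out.append(ss)
    return out


def write_samples(path, samples: list[SampleSet]) -> None:
    rows = []
    for ss in samples:
        for (x, y, z), v in zip(ss.coords, ss.values):
            rows.append((ss.gene_id, x, y, z, v))
    pd.DataFrame(rows, columns=WELL_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# annotation catalogues
# ---------------------------------------------------------------------------

def read_annotations(path, metadata_path=None, population_path=None) -> AnnotationCatalogue:
    """Read a term->gene membership TSV (columns: term_id, gene_id).

    ``metadata_path`` optionally supplies term names/categories (TSV:
    term_id, term_name, category); ``population_path`` optionally supplies
    the reference gene list (one id per line).  Memberships are
    deduplicated; annotated genes absent from the population are added
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise IOFormatError(f"{path}: expected two columns (term_id, gene_id)")
    term_col, gene_col = df.columns[:2]
    meta = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path, sep="\t", dtype=str)
        for _, row in mdf.iterrows():
            meta[row.iloc[0]] = (
                row.iloc[1] if len(row) > 1 else row.iloc[0],
                row.iloc[2] if len(row) > 2 and pd.notna(row.iloc[2]) else None,
            )
    population = set()
    if population_path is not None:
        population = {
            line.strip()
            for line in Path(population_path).read_text().splitlines()
            if line.strip()
        }
    terms: dict[str, set] = {}
    for term_id, grp in df.groupby(term_col, sort=False):
        terms[str(term_id)] = set(grp[gene_col].astype(str))
    if not population:
        population = set().union(*terms.values()) if terms else set()
    catalogue_terms = {
        tid: (meta.get(tid, (tid, None))[0], meta.get(tid, (tid, None))[1], genes)
        for tid, genes in terms.items()
    }
    return AnnotationCatalogue(terms=catalogue_terms, population=frozenset(population))


def write_annotations(path, catalogue: AnnotationCatalogue, metadata_path=None) -> None:
    rows = [
        (tid, gene)
        for tid, (_, _, genes) in catalogue.terms.items()
        for gene in sorted(genes)
    ]
    pd.DataFrame(rows, columns=["term_id", "gene_id"]).to_csv(path, sep="\t", index=False)
    if metadata_path is not None:
        meta_rows = [
            (tid, name, category or "")
            for tid, (name, category, _) in catalogue.terms.items()
        ]
        pd.DataFrame(meta_rows, columns=["term_id", "term_name", "category"]).to_csv(
            metadata_path, sep="\t", index=False
        )
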