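"""Shared site frame: domain geometries, dense maps, sparse samples, annotations.

All pipeline stages operate on a :class:`DomainGeometry` — an indexed set of
analysis sites (voxels of a volumetric grid in world/MNI-style mm
coordinates, or vertices of a cortical surface) with a boolean analysis
mask.  Maps sharing a geometry are index-aligned; mixing geometries is an
error raised eagerly via :func:`require_same_geometry`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from coexmap.errors import GeometryError

VALID_SPACES = ("volume", "surface")
VALID_HEMISPHERES = ("left", "right", "both")
VALID_CATEGORIES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class DomainGeometry:
    """The set of analysis sites shared by every map in one analysis.

    Parameters
    ----------
    coords
        ``(n_sites, 3)`` float array of site coordinates in mm.  For
        volumetric data these are world coordinates (affine applied), so
        that kriging distances are metric; for surfaces they are vertex
        coordinates.
    site_ids
        Unique integer id per site (default: 0..n-1).
    space
        ``"volume"`` or ``"surface"``.
    hemisphere
        ``"left"``, ``"right"`` or ``"both"``.  Cortical analyses default
        to the left hemisphere, where expression sampling is densest.
    mask
        Boolean analysis mask, one entry per site.
    affine, vol_shape, voxel_indices
        Volumetric bookkeeping for NIfTI round-trips: the 4x4 affine, the
        3D array shape, and the ``(n_sites, 3)`` integer voxel index of
        each site.  ``None`` for surfaces.
    """

    coords: np.ndarray
    site_ids: np.ndarray = None
    space: str = "volume"
    hemisphere: str = "left"
    mask: np.ndarray = None
    affine: np.ndarray | None = None
    vol_shape: tuple | None = None
    voxel_indices: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise GeometryError(
                f"coords must be (n_sites, 3); got shape {self.coords.shape}"
            )
        n = self.coords.shape[0]
        if self.site_ids is None:
            self.site_ids = np.arange(n)
        self.site_ids = np.asarray(self.site_ids)
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.site_ids) != n or len(self.mask) != n:
            raise GeometryError(
                "site_ids and mask must match the number of sites "
                f"({len(self.site_ids)}, {len(self.mask)} vs {n})"
            )
        if len(np.unique(self.site_ids)) != n:
            raise GeometryError("site_ids must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("coords must be finite")
        if self.space not in VALID_SPACES:
            raise GeometryError(f"space must be one of {VALID_SPACES}: {self.space!r}")
        if self.hemisphere not in VALID_HEMISPHERES:
            raise GeometryError(
                f"hemisphere must be one of {VALID_HEMISPHERES}: {self.hemisphere!r}"
            )

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def masked_coords(self) -> np.ndarray:
        return self.coords[self.mask]

    def with_mask(self, mask: np.ndarray) -> "DomainGeometry":
        """Return a copy with ``mask`` ANDed onto the current mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_sites,):
            raise GeometryError(
                f"mask length {mask.shape} does not match n_sites {self.n_sites}"
            )
        return DomainGeometry(
            coords=self.coords,
            site_ids=self.site_ids,
            space=self.space,
            hemisphere=self.hemisphere,
            mask=self.mask & mask,
            affine=self.affine,
            vol_shape=self.vol_shape,
            voxel_indices=self.voxel_indices,
        )

    def same_frame(self, other: "DomainGeometry") -> bool:
        return (
            self.space == other.space
            and self.n_sites == other.n_sites
            and np.array_equal(self.site_ids, other.site_ids)
            and np.allclose(self.coords, other.coords)
        )


def require_same_geometry(a: DomainGeometry, b: DomainGeometry) -> None:
    """Raise :class:`GeometryError` unless ``a`` and ``b`` share a site frame."""
    if not a.same_frame(b):
        raise GeometryError(
            "maps use different geometries "
            f"({a.space}/{a.n_sites} sites vs {b.space}/{b.n_sites} sites); "
            "all stages require index-aligned maps"
        )


@dataclass
class TargetMap:
    """A dense scalar map on a geometry (e.g. PET BP_ND, dimensionless).

    ``values`` has one entry per site; entries outside the mask may be NaN.
    """

    geometry: DomainGeometry
    values: np.ndarray
    name: str = "target"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.n_sites,):
            raise GeometryError(
                f"values length {self.values.shape} does not match "
                f"n_sites {self.geometry.n_sites}"
            )
        if not np.all(np.isfinite(self.values[self.geometry.mask])):
            raise GeometryError("values must be finite on the mask")

    def masked_values(self) -> np.ndarray:
        return self.values[self.geometry.mask]

    @property
    def sd(self) -> float:
        """Sample standard deviation (divisor n-1) over masked sites."""
        return float(np.std(self.masked_values(), ddof=1))


@dataclass
class SampleSet:
    """Sparse measurements of one gene at well sites.

    ``coords`` is ``(n_wells, 3)`` in mm; ``values`` are log2 expression
    intensities.  At least 3 wells are required for variogram fitting;
    sets below that are loadable but flagged ``unfittable``.
    """

    gene_id: str
    coords: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.coords.shape != (len(self.values), 3):
            raise GeometryError(
                f"gene {self.gene_id}: coords shape {self.coords.shape} does not "
                f"match {len(self.values)} values"
            )

    @property
    def n_wells(self) -> int:
        return len(self.values)

    @property
    def fittable(self) -> bool:
        return self.n_wells >= 3

    def dedupe(self) -> "SampleSet":
        """Average values observed at duplicate coordinates (with warning)."""
        uniq, inverse = np.unique(self.coords, axis=0, return_inverse=True)
        if len(uniq) == self.n_wells:
            return self
        sums = np.zeros(len(uniq))
        counts = np.zeros(len(uniq))
        np.add.at(sums, inverse, self.values)
        np.add.at(counts, inverse, 1)
        warnings.warn(
            f"gene {self.gene_id}: {self.n_wells - len(uniq)} duplicate "
            "well coordinates averaged",
            stacklevel=2,
        )
        # np.unique sorts rows; restore first-appearance order
        order = np.argsort([np.min(np.where(inverse == i)[0]) for i in range(len(uniq))])
        return SampleSet(self.gene_id, uniq[order], (sums / counts)[order])


@dataclass
class AnnotationCatalogue:
    """Term -> gene membership lists plus the reference gene population.

    ``terms`` maps term_id to ``(term_name, category, frozenset of gene
    ids)``.  Every annotated gene belongs to ``population``.
    """

    terms: Mapping[str, tuple]
    population: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.terms = dict(self.terms)
        pop = set(self.population)
        stray = set()
        for term_id, (name, category, genes) in list(self.terms.items()):
            if category is not None and category not in VALID_CATEGORIES:
                raise ValueError(
                    f"term {term_id}: category must be one of "
                    f"{VALID_CATEGORIES}: {category!r}"
                )
            genes = frozenset(genes)
            self.terms[term_id] = (name, category, genes)
            stray |= genes - pop
        if stray:
            warnings.warn(
                f"{len(stray)} annotated genes were missing from the population "
                "list and were added",
                stacklevel=2,
            )
            pop |= stray
        self.population = frozenset(pop)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def n_genes(self) -> int:
        return len(self.population)

    def term_genes(self, term_id: str) -> frozenset:
        return self.terms[term_id][2]


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distance vector (scipy ``pdist`` convention)."""
    from scipy.spatial.distance import pdist

    return pdist(np.asarray(coords, dtype=float))


def cross_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Dense Euclidean distance matrix between two coordinate sets."""
    from scipy.spatial.distance import cdist

    return cdist(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
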