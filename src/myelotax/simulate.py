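"""Synthetic data generators emulating the statistical structure of the study inputs.

Three generators cover the pipeline's input modalities:

* :func:`generate_count_matrix` — negative-binomial gene x cell counts with
  planted module-specific expression programs (the disease-driven programs
  behind the supercluster gene modules);
* :func:`generate_spatial_scene` — point patterns of typed cells in a µm field
  (uniform or Gaussian-clustered), as produced by targeted in-situ platforms;
* :func:`generate_binned_scene` — a 2-µm spot grid of transcript counts drawn
  from circular/polygonal nuclei, with the ground-truth nucleus x gene matrix
  kept for recovery tests.

All generators are pure functions of (spec, seed): the top-level seed is split
deterministically per sub-generator via :class:`numpy.random.SeedSequence`.
:func:`load_fixture_modules` exposes the eight published supercluster gene
modules per species, symbols stored exactly as printed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from shapely.geometry import Point, Polygon

__all__ = [
    "ProgramSpec",
    "SpatialSceneSpec",
    "BinnedSceneSpec",
    "NucleusSpec",
    "generate_count_matrix",
    "generate_spatial_scene",
    "generate_binned_scene",
    "load_fixture_modules",
]


@dataclass(frozen=True)
class ProgramSpec:
    """A planted expression program: module genes up-regulated by `fold_change`
    over a flat negative-binomial baseline."""

    program_name: str
    module_genes: tuple[str, ...]
    fold_change: float = 8.0
    baseline_mean: float = 0.5
    dispersion: float = 2.0  # NB size parameter (mean/size parameterization)

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if not self.module_genes:
            raise ValueError("module_genes must be non-empty")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")


@dataclass(frozen=True)
class SpatialSceneSpec:
    """Layout of typed cells in a rectangular µm field.

    ``cell_types`` maps a label to (count, mode) where mode is either
    ``("uniform",)`` or ``("clustered", (cx, cy), sd)``.
    """

    field_width_um: float = 1000.0
    field_height_um: float = 1000.0
    cell_types: tuple[tuple[str, int, tuple], ...] = ()
    min_separation_um: float = 0.0

    def __post_init__(self) -> None:
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be positive")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be nonnegative")
        for label, count, mode in self.cell_types:
            if count < 0:
                raise ValueError(f"negative count for {label!r}")
            if mode[0] not in ("uniform", "clustered"):
                raise ValueError(f"unknown spatial mode {mode[0]!r}")


@dataclass(frozen=True)
class NucleusSpec:
    """One nucleus: a circle (center, radius) or explicit polygon, plus its
    expected transcript count per gene."""

    nucleus_id: str
    profile: Mapping[str, int]
    center: tuple[float, float] | None = None
    radius_um: float | None = None
    polygon: Sequence[tuple[float, float]] | None = None

    def geometry(self) -> Polygon:
        if self.polygon is not None:
            return Polygon(self.polygon)
        if self.center is None or self.radius_um is None:
            raise ValueError(f"nucleus {self.nucleus_id!r} needs a circle or polygon")
        return Point(self.center).buffer(self.radius_um, quad_segs=16)


@dataclass(frozen=True)
class BinnedSceneSpec:
    nuclei: tuple[NucleusSpec, ...]
    spot_pitch_um: float = 2.0

    def __post_init__(self) -> None:
        if self.spot_pitch_um <= 0:
            raise ValueError("spot_pitch_um must be positive")
        for nuc in self.nuclei:
            if any(v < 0 for v in nuc.profile.values()):
                raise ValueError(f"negative profile entry for nucleus {nuc.nucleus_id!r}")


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_count_matrix(
    programs: Sequence[ProgramSpec],
    cells_per_program: int,
    n_background_genes: int,
    metadata_plan: Mapping[str, tuple[str, str, str]] | None = None,
    seed: int = 0,
    cell_type: str = "Microglia",
) -> AnnData:
    """Sparse NB counts with planted programs; cells x genes AnnData.

    Cells of program *p* draw p's module genes from NB(mean = baseline x fold),
    all other genes from NB(mean = baseline). ``metadata_plan`` maps a program
    name to (condition, region, species); unmapped programs get placeholder
    metadata. ``obs['true_program']`` records the planted label.
    """
    if cells_per_program <= 0:
        raise ValueError("cells_per_program must be positive")
    if not programs:
        raise ValueError("at least one program is required")

    module_union: list[str] = []
    seen = set()
    for p in programs:
        for g in p.module_genes:
            if g not in seen:
                seen.add(g)
                module_union.append(g)
    genes = module_union + [f"BG{i:05d}" for i in range(n_background_genes)]
    if len(genes) < len(seen):
        raise ValueError("gene universe smaller than the union of module genes")
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    rngs = _rngs(seed, len(programs))
    blocks, obs_rows = [], []
    for p, rng in zip(programs, rngs):
        mean = np.full(n_genes, p.baseline_mean)
        idx = [gene_index[g] for g in p.module_genes]
        mean[idx] = p.baseline_mean * p.fold_change
        size = p.dispersion
        # NB(mean, size): numpy parameterizes by (n=size, p=size/(size+mean))
        counts = rng.negative_binomial(size, size / (size + mean), size=(cells_per_program, n_genes))
        blocks.append(sp.csr_matrix(counts))
        condition, region, species = (
            metadata_plan.get(p.program_name, ("control", "cortex", "human"))
            if metadata_plan
            else ("control", "cortex", "human")
        )
        for i in range(cells_per_program):
            obs_rows.append(
                {
                    "sample": f"{p.program_name}_s0",
                    "condition": condition,
                    "region": region,
                    "species": species,
                    "cell_type": cell_type,
                    "true_program": p.program_name,
                }
            )

    x = sp.vstack(blocks, format="csr")
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i:06d}" for i in range(x.shape[0])]
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    return AnnData(X=x, obs=obs, var=var)


def generate_spatial_scene(spec: SpatialSceneSpec, seed: int = 0) -> pd.DataFrame:
    """Typed cell point pattern; columns cell_id, x_um, y_um, identity, fov."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows: list[tuple[str, float, float, str]] = []
    placed: list[tuple[float, float]] = []
    max_tries = 200

    def _ok(x: float, y: float) -> bool:
        if spec.min_separation_um == 0:
            return True
        d2min = spec.min_separation_um**2
        return all((x - px) ** 2 + (y - py) ** 2 >= d2min for px, py in placed)

    counter = 0
    for label, count, mode in spec.cell_types:
        for _ in range(count):
            for attempt in range(max_tries):
                if mode[0] == "uniform":
                    x = rng.uniform(0, spec.field_width_um)
                    y = rng.uniform(0, spec.field_height_um)
                else:
                    (cx, cy), sd = mode[1], mode[2]
                    x = rng.normal(cx, sd)
                    y = rng.normal(cy, sd)
                    if not (0 <= x <= spec.field_width_um and 0 <= y <= spec.field_height_um):
                        continue
                if _ok(x, y):
                    break
            else:
                raise RuntimeError(
                    f"could not place cell of type {label!r} with min_separation="
                    f"{spec.min_separation_um} after {max_tries} tries"
                )
            placed.append((x, y))
            rows.append((f"sc{counter:06d}", x, y, label))
            counter += 1
    return pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um", "identity"]).assign(fov="fov0")


def generate_binned_scene(
    spec: BinnedSceneSpec, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, Polygon], pd.DataFrame]:
    """Place each nucleus's transcripts uniformly inside it and snap them to the
    spot grid.

    Returns (spot table with columns barcode/x_um/y_um/gene/count, mapping
    nucleus_id -> undilated polygon, truth nucleus x gene count matrix).
    Transcript totals are conserved between spot table and truth matrix.
    """
    rngs = _rngs(seed, max(len(spec.nuclei), 1))
    pitch = spec.spot_pitch_um
    spot_counts: dict[tuple[float, float, str], int] = {}
    polygons: dict[str, Polygon] = {}
    genes = sorted({g for nuc in spec.nuclei for g in nuc.profile})
    truth = pd.DataFrame(
        0, index=[n.nucleus_id for n in spec.nuclei], columns=genes, dtype=int
    )

    for nuc, rng in zip(spec.nuclei, rngs):
        geom = nuc.geometry()
        polygons[nuc.nucleus_id] = geom
        minx, miny, maxx, maxy = geom.bounds
        for gene, n_tx in nuc.profile.items():
            placed = 0
            while placed < n_tx:
                x = rng.uniform(minx, maxx)
                y = rng.uniform(miny, maxy)
                if not geom.covers(Point(x, y)):
                    continue
                gx = round(x / pitch) * pitch
                gy = round(y / pitch) * pitch
                key = (gx, gy, gene)
                spot_counts[key] = spot_counts.get(key, 0) + 1
                placed += 1
            truth.loc[nuc.nucleus_id, gene] += int(n_tx)

    rows = [
        {"barcode": f"spot_{gx:.0f}_{gy:.0f}", "x_um": gx, "y_um": gy, "gene": gene, "count": c}
        for (gx, gy, gene), c in sorted(spot_counts.items())
    ]
    spots = pd.DataFrame(rows, columns=["barcode", "x_um", "y_um", "gene", "count"])
    return spots, polygons, truth


def load_fixture_modules(species: str) -> dict[str, list[str]]:
    """The eight published supercluster gene modules for 'human' or 'mouse'.

    Gene symbols are stored exactly as printed (human upper-case, mouse
    title-case); no symbol normalization is applied.
    """
    if species not in ("human", "mouse"):
        raise ValueError(f"unknown species {species!r}; expected 'human' or 'mouse'")
    path = resources.files("myelotax.data").joinpath(f"gene_modules_{species}.json")
    payload = json.loads(path.read_text())
    return {name: list(genes) for name, genes in payload["modules"].items()}
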