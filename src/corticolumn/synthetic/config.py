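"""Configuration for the synthetic cortical-column data generator.

The generator emulates the statistical structure of a two-species (mouse vs.
opossum) V1 cell-type survey: an intratelencephalic (IT) expression continuum
spanned by one archetype per cortical layer (2/3, 4, 5, 6), discrete non-IT
subclasses with marker genes, negative-binomial UMI counts with
species-specific sequencing depth, laminar depth distributions per subclass,
and PV/WFA immunofluorescence fields with or without PV-centered perineuronal
rings.  Species presets differ only in the fields documented on
:func:`species_preset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import numpy as np

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "species_preset",
    "it_preset",
    "IT_SUBCLASSES",
    "NON_IT_GLUT_SUBCLASSES",
    "GABA_SUBCLASSES",
    "NONNEURONAL_SUBCLASSES",
]

# Subclass vocabularies.  IT subclasses are named per species (mouse layers vs.
# opossum IT_A-D); both map onto the same four archetypes.
IT_SUBCLASSES = {
    "mouse": ("L2/3", "L4", "L5IT", "L6IT"),
    "opossum": ("IT_A", "IT_B", "IT_C", "IT_D"),
}
NON_IT_GLUT_SUBCLASSES = ("L5PT", "L5NP", "L6CT", "L6b")
GABA_SUBCLASSES = ("Pvalb", "Sst", "Vip", "Lamp5", "Frem1")
NONNEURONAL_SUBCLASSES = ("Astro", "Oligo", "OPC", "Micro")

def subclass_to_class(name: str) -> str:
    """Map a subclass label to its cell class."""
    if name in GABA_SUBCLASSES:
        return "gabaergic"
    if name in NONNEURONAL_SUBCLASSES:
        return "nonneuronal"
    return "glutamatergic"


# Preferred subpial depth (um) of each IT archetype, one per modeled layer.
# Column height defaults to 1000 um (top of layer 2/3 to bottom of layer 6).
ARCHETYPE_DEPTHS_UM = (130.0, 380.0, 600.0, 850.0)


def _default_depth_law() -> dict[str, tuple[float, float]]:
    """Per-subclass (mean, sd) of truncated-normal subpial depth in um."""
    law = {
        "L5PT": (620.0, 70.0),
        "L5NP": (650.0, 90.0),
        "L6CT": (860.0, 60.0),
        "L6b": (970.0, 30.0),
        "Pvalb": (500.0, 220.0),
        "Sst": (550.0, 220.0),
        "Vip": (250.0, 150.0),
        "Lamp5": (200.0, 150.0),
        "Frem1": (300.0, 180.0),
        "Astro": (500.0, 280.0),
        "Oligo": (750.0, 180.0),
        "OPC": (500.0, 280.0),
        "Micro": (500.0, 280.0),
    }
    # IT subclasses track their archetype's home layer.
    for species, names in IT_SUBCLASSES.items():
        for name, d in zip(names, ARCHETYPE_DEPTHS_UM):
            law[name] = (d, 90.0)
    return law


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic generator.

    Parameters
    ----------
    n_cells, n_genes
        Problem size; both must be positive.
    species_preset
        ``"mouse"`` or ``"opossum"``; see :func:`species_preset`.
    it_archetypes
        Number of IT archetypes (one per modeled layer; default 4).
    archetype_concentration
        Dirichlet concentration per archetype for IT mixture weights.  Values
        below 1 pile cells near polytope vertices (mouse-like); the opossum
        preset spreads mass across the A-B-C face.
    noise_sd
        SD of Gaussian noise added to the latent (pre-count) IT expression.
    nb_dispersion
        Negative-binomial shape parameter (larger = closer to Poisson).
    class_proportions, glut_it_fraction, gabaergic_proportions,
    nonneuronal_proportions
        Composition of the simulated tissue.  All simplex vectors must sum
        to 1 within 1e-9.
    mean_log_umis, sd_log_umis
        Log-normal per-cell library-size model (species-specific depth).
    depth_law
        subclass -> (mean_um, sd_um) truncated-normal subpial depth.
    column_height_um, column_width_um
        Spatial column geometry for :func:`generate_spatial`.
    pv_density_per_mm2
        Poisson intensity of PV centroids for :func:`generate_histo`.
    pnn_mode
        ``"pv_centered"`` paints WFA rings at PV centroids,
        ``"deep_layer_random"`` at random deep-layer sites away from PV cells,
        ``"none"`` paints no rings.
    seed
        Base seed; identical config + seed gives bit-identical output.
    """

    n_cells: int = 2000
    n_genes: int = 2000
    species_preset: str = "mouse"
    it_archetypes: int = 4
    archetype_concentration: tuple[float, ...] = (0.3, 0.3, 0.3, 0.3)
    noise_sd: float = 0.15
    nb_dispersion: float = 4.0
    class_proportions: dict = field(
        default_factory=lambda: {
            "glutamatergic": 0.60,
            "gabaergic": 0.20,
            "nonneuronal": 0.20,
        }
    )
    glut_it_fraction: float = 0.70
    non_it_glut_proportions: dict = field(
        default_factory=lambda: {"L5PT": 0.3, "L5NP": 0.15, "L6CT": 0.4, "L6b": 0.15}
    )
    gabaergic_proportions: dict = field(
        default_factory=lambda: {
            "Pvalb": 0.35, "Sst": 0.30, "Vip": 0.15, "Lamp5": 0.12, "Frem1": 0.08,
        }
    )
    nonneuronal_proportions: dict = field(
        default_factory=lambda: {"Astro": 0.35, "Oligo": 0.35, "OPC": 0.15, "Micro": 0.15}
    )
    mean_log_umis: float = float(np.log(6000.0))
    sd_log_umis: float = 0.35
    n_samples: int = 4
    depth_law: dict = field(default_factory=_default_depth_law)
    column_height_um: float = 1000.0
    column_width_um: float = 300.0
    pv_density_per_mm2: float = 300.0
    pnn_mode: str = "pv_centered"
    histo_px_size_um: float = 4.0
    histo_field_mm: tuple[float, float] = (2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_genes <= 0:
            raise ValueError("n_cells must be >= 0 and n_genes positive")
        if self.species_preset not in ("mouse", "opossum"):
            raise ValueError(f"unknown species preset {self.species_preset!r}")
        if len(self.archetype_concentration) != self.it_archetypes:
            raise ValueError("archetype_concentration length must equal it_archetypes")
        if any(a <= 0 for a in self.archetype_concentration):
            raise ValueError("archetype concentrations must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.pnn_mode not in ("pv_centered", "deep_layer_random", "none"):
            raise ValueError(f"unknown pnn_mode {self.pnn_mode!r}")
        for name, simplex in [
            ("class_proportions", self.class_proportions),
            ("non_it_glut_proportions", self.non_it_glut_proportions),
            ("gabaergic_proportions", self.gabaergic_proportions),
            ("nonneuronal_proportions", self.nonneuronal_proportions),
        ]:
            total = float(sum(simplex.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total!r})")
            if any(v < 0 for v in simplex.values()):
                raise ValueError(f"{name} has negative entries")

    @property
    def it_subclass_names(self) -> tuple[str, ...]:
        return IT_SUBCLASSES[self.species_preset][: self.it_archetypes]

    def with_(self, **kw) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground-truth record emitted next to every generated dataset."""

    subclass: np.ndarray  # per-cell subclass label
    cell_class: np.ndarray  # per-cell class label
    archetype_weights: np.ndarray  # cells x K simplex rows (zero rows for non-IT)
    depth_um: np.ndarray | None  # per-cell depth (spatial generator only)
    proportions: Mapping[str, float]  # generative subclass proportions
    density_ratio: float | None = None  # generative PV density contrast
    pnn_mode: str | None = None


def species_preset(species: str, **overrides) -> GeneratorConfig:
    """Config preset for one species.

    The two presets differ only in:

    - ``archetype_concentration`` — mouse concentrates IT cells near the
      polytope vertices; opossum spreads them across the A-B-C face (lower
      weight on the fourth archetype, near-uniform mass over the first three);
    - ``gabaergic_proportions`` — Pvalb 0.35 (mouse) vs. 0.50 (opossum);
    - ``mean_log_umis`` — opossum libraries are shallower;
    - ``pv_density_per_mm2`` — opossum 1.2x the mouse density;
    - ``pnn_mode`` — PV-centered rings in mouse, random deep-layer rings in
      opossum.
    """
    if species == "mouse":
        cfg = GeneratorConfig(species_preset="mouse")
    elif species == "opossum":
        cfg = GeneratorConfig(
            species_preset="opossum",
            archetype_concentration=(1.0, 1.0, 1.0, 0.25),
            gabaergic_proportions={
                "Pvalb": 0.50, "Sst": 0.27, "Vip": 0.10, "Lamp5": 0.08, "Frem1": 0.05,
            },
            mean_log_umis=float(np.log(3000.0)),
            pv_density_per_mm2=360.0,
            pnn_mode="deep_layer_random",
        )
    else:
        raise ValueError(f"unknown species {species!r}")
    return cfg.with_(**overrides) if overrides else cfg


def it_preset(n_cells: int = 2000, n_genes: int = 300, seed: int = 0, **overrides) -> GeneratorConfig:
    """Default IT-continuum preset: every cell is an IT neuron.

    Used for archetype-recovery analyses where only the four-vertex IT
    continuum matters.
    """
    cfg = GeneratorConfig(
        n_cells=n_cells,
        n_genes=n_genes,
        class_proportions={"glutamatergic": 1.0, "gabaergic": 0.0, "nonneuronal": 0.0},
        glut_it_fraction=1.0,
        seed=seed,
    )
    return cfg.with_(**overrides) if overrides else cfg
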