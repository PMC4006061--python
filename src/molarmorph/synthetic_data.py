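"""Synthetic landmark studies with designed statistical structure.

The generator emulates a case-control crown-form study: four groups
(control and three increasingly severe hypodontia grades) by two sexes
with slightly unbalanced cells, a declining group mean centroid size,
group mean-shape offsets of designed Procrustes magnitude that grow with
severity, weak allometry, isotropic landmark noise, and a replicated
individual / scan-session / digitization hierarchy for error studies.

Shape effects are specified as tangent vectors at the template (small-
deformation regime): a designed offset of Procrustes norm c between two
groups produces, after GPA, a mean-shape Procrustes distance of c up to
O(c^2) renormalization terms and sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DesignError
from .landmark_io import (
    GROUPS,
    LandmarkConfiguration,
    SpecimenRecord,
    StudyDataset,
    default_molar_schema,
)
from .procrustes import centroid_size

# Raw template coordinates (mm): x mesiodistal, y buccolingual (buccal
# positive), z occlusogingival (occlusal positive). Synthetic fixture
# shaped to respect molar crown topology: cusp tips above pits, gingival
# margin below the occlusal surface, contacts at opposite ends.
_TEMPLATE_RAW = np.array(
    [
        [-5.5, 0.0, 2.5],  # mesial_contact
        [5.5, 0.0, 2.5],  # distal_contact
        [0.0, 5.4, 1.5],  # buccal_axis_endpoint
        [-2.8, -3.8, 7.2],  # mesiolingual_cusp_tip
        [2.6, -3.7, 7.0],  # distolingual_cusp_tip
        [-3.0, 3.6, 6.8],  # mesiobuccal_cusp_tip
        [1.8, 3.8, 6.6],  # distobuccal_cusp_tip
        [4.6, 2.2, 6.2],  # hypoconulid_tip
        [-4.0, 0.2, 4.8],  # outer_mesial_pit
        [-2.2, 0.1, 4.5],  # inner_mesial_pit
        [0.3, 0.0, 4.4],  # central_pit
        [2.9, -0.2, 4.6],  # distal_pit
        [-4.8, 3.4, -0.5],  # mesial_papilla_end
        [0.0, 4.6, -1.0],  # gingival_margin_midpoint
        [4.6, 3.2, -0.6],  # distal_papilla_end
        [-0.4, 4.4, 5.2],  # buccal_groove_occlusal_limit
        [3.4, 3.2, 5.4],  # distobuccal_groove_occlusal_limit
        [0.0, -4.2, 5.6],  # lingual_groove_occlusal_limit
    ]
)

#: centroid size (mm) the template is normalized to
TEMPLATE_CS = 18.2


def template_molar() -> LandmarkConfiguration:
    """Fixed synthetic 18-landmark lower-first-molar crown template.

    Deterministic; rescaled so its centroid size is exactly
    ``TEMPLATE_CS`` mm, within the realistic molar range.
    """
    coords = _TEMPLATE_RAW * (TEMPLATE_CS / centroid_size(_TEMPLATE_RAW))
    return LandmarkConfiguration("template", coords, default_molar_schema())


def _similarity_constraint_basis(template_unit: np.ndarray) -> np.ndarray:
    """Orthonormal basis (7 x 3k) of the similarity directions at a shape.

    Rows span translations (3), scaling (1) and infinitesimal rotations
    (3) of the unit-CS, centered configuration; tangent shape vectors are
    orthogonal to all of them.
    """
    k = template_unit.shape[0]
    rows = []
    for a in range(3):
        t = np.zeros((k, 3))
        t[:, a] = 1.0
        rows.append(t.ravel())
    rows.append(template_unit.ravel())
    gens = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),
        np.array([[0, 0, -1], [0, 0, 0], [1, 0, 0]], dtype=float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
    ]
    for A in gens:
        rows.append((template_unit @ A.T).ravel())
    C = np.stack(rows)
    # orthonormalize
    Q, _ = np.linalg.qr(C.T)
    return Q.T[: len(rows)]


def tangent_directions(template_unit: np.ndarray, n: int, seed: int) -> np.ndarray:
    """n orthonormal random directions in the tangent space at a shape.

    Deterministic given ``seed``; each direction is orthogonal to the
    translation/scale/rotation similarity directions and to the others.
    """
    k3 = template_unit.size
    C = _similarity_constraint_basis(template_unit)
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n, k3))
    raw -= (raw @ C.T) @ C
    out = []
    for v in raw:
        for u in out:
            v = v - (v @ u) * u
        v = v / np.linalg.norm(v)
        out.append(v)
    return np.stack(out)


@dataclass
class ErrorDesign:
    """Replicated measurement-error design: individuals x scans x digitizations."""

    n_individuals: int = 20
    n_scans: int = 2
    n_digitizations: int = 2
    scan_sd: float = 0.022  # mm, per coordinate, between scan sessions
    digit_sd: float = 0.083  # mm, per coordinate, between digitizations


@dataclass
class GeneratorSpec:
    """Design parameters of a synthetic crown-form study.

    ``group_shape_offsets`` are tangent vectors (length 3k, unit-CS
    scale) added to the template shape per group; their norms are the
    designed mean-shape Procrustes distances from the control group.
    ``allometry_vector`` is the tangent shape change per mm of centroid
    size. ``landmark_noise_sd`` is the isotropic per-coordinate noise in
    mm at template scale (specimen-level biological + digitization
    variation for single-replicate studies).
    """

    template: np.ndarray
    cell_sizes: dict[tuple[str, str], int]
    group_shape_offsets: dict[str, np.ndarray]
    severity_order: tuple[str, ...] = GROUPS
    sex_size_effect: float = 0.44  # mm added to male mean CS
    group_size_means: dict[str, float] = field(
        default_factory=lambda: {
            "control": 18.58,
            "mild": 17.88,
            "moderate": 17.84,
            "severe": 17.51,
        }
    )
    size_sd: float = 1.05  # mm
    allometry_vector: np.ndarray | None = None
    landmark_noise_sd: float = 0.16  # mm
    error_design: ErrorDesign = field(default_factory=ErrorDesign)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_sd < 0 or self.landmark_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if any(n < 0 for n in self.cell_sizes.values()):
            raise ValueError("cell sizes must be non-negative")

    def with_seed(self, seed: int) -> "GeneratorSpec":
        return replace(self, seed=seed)

    def expected_grand_mean_cs(self) -> float:
        """Design (not sample) grand mean CS over all cells."""
        total = sum(self.cell_sizes.values())
        acc = 0.0
        for (g, s), n in self.cell_sizes.items():
            acc += n * (self.group_size_means[g] + (self.sex_size_effect if s == "M" else 0.0))
        return acc / total


#: designed mean-shape Procrustes distances from control, by severity
DEFAULT_OFFSET_NORMS = {"control": 0.0, "mild": 0.035, "moderate": 0.045, "severe": 0.055}

#: designed allometric shape change per mm CS (tangent norm)
DEFAULT_ALLOMETRY_NORM = 0.016

#: fixed seed versioning the default offset/allometry directions
_DIRECTION_SEED = 12345


def default_study_spec(seed: int = 0) -> GeneratorSpec:
    """The default study design: unbalanced 4 x 2 cells, severity-graded
    mean sizes and shape offsets, weak (~7% of shape variance) allometry.

    Group offsets share a common severity direction (70% of their norm)
    plus a group-specific orthogonal component, so mean shapes order
    along the severity gradient while remaining distinguishable.
    """
    template = template_molar().coords
    unit = (template - template.mean(axis=0)) / centroid_size(template)
    dirs = tangent_directions(unit, 5, _DIRECTION_SEED)
    common, specific = dirs[0], dirs[1:4]
    c, s = np.sqrt(0.7), np.sqrt(0.3)
    offsets = {"control": np.zeros(unit.size)}
    for vec, grp in zip(specific, ("mild", "moderate", "severe")):
        offsets[grp] = DEFAULT_OFFSET_NORMS[grp] * (c * common + s * vec)
    cells = {
        ("control", "F"): 20,
        ("mild", "F"): 20,
        ("moderate", "F"): 20,
        ("severe", "F"): 19,
        ("control", "M"): 20,
        ("mild", "M"): 20,
        ("moderate", "M"): 19,
        ("severe", "M"): 15,
    }
    return GeneratorSpec(
        template=template,
        cell_sizes=cells,
        group_shape_offsets=offsets,
        allometry_vector=DEFAULT_ALLOMETRY_NORM * dirs[4],
        seed=seed,
    )


def designed_error_shares(spec: GeneratorSpec) -> dict[str, float]:
    """Expected percent-explained shares of the hierarchical error ANOVA.

    From the design's variance components (per coordinate, isotropic):
    E[SS_ind] = (n-1)(S D si^2 + D ss^2 + sd^2),
    E[SS_scan] = n (S-1)(D ss^2 + sd^2), E[SS_digit] = n S (D-1) sd^2,
    with si/ss/sd the individual / scan / digitization noise sds. Shares
    are invariant to the uniform Procrustes rescaling of the noise.
    """
    ed = spec.error_design
    n, S, D = ed.n_individuals, ed.n_scans, ed.n_digitizations
    si2, ss2, sd2 = spec.landmark_noise_sd**2, ed.scan_sd**2, ed.digit_sd**2
    ss = np.array(
        [
            (n - 1) * (S * D * si2 + D * ss2 + sd2),
            n * (S - 1) * (D * ss2 + sd2),
            n * S * (D - 1) * sd2,
        ]
    )
    shares = 100.0 * ss / ss.sum()
    return {"individual": shares[0], "scan_error": shares[1], "digitization_error": shares[2]}


def designed_allometric_share(spec: GeneratorSpec) -> float:
    """Expected percent of within-group shape variance predicted by CS.

    The allometric tangent variance is |allometry_vector|^2 var(CS); the
    residual shape variance from isotropic landmark noise occupies the
    3k - 7 shape dimensions with per-coordinate variance
    (landmark_noise_sd / template CS)^2.
    """
    if spec.allometry_vector is None:
        return 0.0
    k = np.asarray(spec.template).shape[0]
    beta2 = float(np.sum(np.asarray(spec.allometry_vector) ** 2))
    allo_var = beta2 * spec.size_sd**2
    noise_var = (3 * k - 7) * (spec.landmark_noise_sd / TEMPLATE_CS) ** 2
    return 100.0 * allo_var / (allo_var + noise_var)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def generate_study(spec: GeneratorSpec, seed: int | None = None) -> StudyDataset:
    """Simulate a single-replicate crown-form study from a design spec.

    Each specimen's shape is the unit-CS template plus its group offset,
    the allometric term ``allometry_vector * (CS - design grand mean)``
    and isotropic landmark noise; the configuration is then scaled to a
    centroid size drawn from the (group, sex) cell's normal distribution
    and randomly rotated and translated. Bit-identical for a given spec
    and seed.
    """
    if sum(spec.cell_sizes.values()) == 0:
        raise DesignError("spec generates zero specimens")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    template = np.asarray(spec.template, dtype=float)
    k = template.shape[0]
    unit = (template - template.mean(axis=0)) / centroid_size(template)
    grand_cs = spec.expected_grand_mean_cs()
    allo = (
        np.zeros(3 * k) if spec.allometry_vector is None else np.asarray(spec.allometry_vector)
    )
    if k == 18:
        schema = default_molar_schema()
    else:
        from .landmark_io import LandmarkSchema

        schema = LandmarkSchema(tuple(f"lm{j + 1}" for j in range(k)))

    configs, records = [], []
    for (group, sex), n in sorted(spec.cell_sizes.items()):
        offset = np.asarray(spec.group_shape_offsets.get(group, np.zeros(3 * k)))
        mean_cs = spec.group_size_means[group] + (spec.sex_size_effect if sex == "M" else 0.0)
        for i in range(n):
            cs_i = rng.normal(mean_cs, spec.size_sd)
            shape = unit + (offset + allo * (cs_i - grand_cs)).reshape(k, 3)
            coords = shape * centroid_size(template)
            coords = coords + rng.normal(0.0, spec.landmark_noise_sd, size=(k, 3))
            coords = coords - coords.mean(axis=0)
            coords = coords * (cs_i / centroid_size(coords))
            coords = coords @ _random_rotation(rng).T + rng.normal(0.0, 10.0, 3)
            sid = f"{group}_{sex}_{i + 1:03d}"
            configs.append(LandmarkConfiguration(sid, coords, schema))
            records.append(SpecimenRecord(sid, group, sex))
    return StudyDataset(configs, records)


def generate_error_study(spec: GeneratorSpec, seed: int | None = None) -> StudyDataset:
    """Simulate a replicated error study with hierarchical noise.

    Each individual receives one base configuration (template plus
    individual-level landmark noise, scaled to an individual centroid
    size); each scan session adds a scan-level perturbation shared by its
    digitizations; each digitization adds its own perturbation and an
    arbitrary rotation/translation. Specimen ids encode the hierarchy as
    ``ind<i>:s<scan>:d<digit>`` with matching replicate labels.
    """
    ed = spec.error_design
    if ed.n_scans < 2 or ed.n_digitizations < 2:
        raise DesignError("error design needs >= 2 scans and >= 2 digitizations per scan")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    template = np.asarray(spec.template, dtype=float)
    k = template.shape[0]
    schema = default_molar_schema() if k == 18 else None
    if schema is None:
        from .landmark_io import LandmarkSchema

        schema = LandmarkSchema(tuple(f"lm{j + 1}" for j in range(k)))

    configs, records = [], []
    for i in range(ed.n_individuals):
        cs_i = rng.normal(TEMPLATE_CS, spec.size_sd)
        base = template * (cs_i / centroid_size(template))
        base = base + rng.normal(0.0, spec.landmark_noise_sd, size=(k, 3))
        for s in range(1, ed.n_scans + 1):
            scan_pert = rng.normal(0.0, ed.scan_sd, size=(k, 3))
            for d in range(1, ed.n_digitizations + 1):
                coords = base + scan_pert + rng.normal(0.0, ed.digit_sd, size=(k, 3))
                coords = coords @ _random_rotation(rng).T + rng.normal(0.0, 10.0, 3)
                sid = f"ind{i + 1:03d}:s{s}:d{d}"
                configs.append(LandmarkConfiguration(sid, coords, schema))
                records.append(
                    SpecimenRecord(sid, "control", "F", scan_session=s, digitization=d)
                )
    return StudyDataset(configs, records)
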