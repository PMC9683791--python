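"""Synthetic fixtures with planted ground truth for every analysis stage.

Each generator returns its fixture together with a plain-dict
``PlantedTruth`` record of every ground-truth quantity the fixture
encodes (transforms, volumes, extents, hotspot counts, kinetic
parameters, seeds), so analysis operations can be tested for recovery
without external downloads. Helix-bundle fixtures are C-alpha-only
pseudo-structures; cavity shells use generic pseudo-atoms at the default
vdW radius. All randomness flows through one explicit seeded
``numpy.random.Generator`` — no global state, same seed means a
bit-identical fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeneratorError, ValidationError
from .kinetics import KineticsDataset, MeltCurve, mm_rate
from .pockets import DEFAULT_VDW
from .structure_model import (
    AtomRecord,
    LigandInstance,
    Residue,
    ResidueRef,
    SegmentAnnotation,
    StructureModel,
)

AA_FOR_SAMPLING = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class HelixSpec:
    """Ideal helix: residue i sits at origin + i*rise*axis + radius on the
    rotating normal. Defaults approximate an alpha helix (rise 1.5 A/res,
    twist 100 deg/res, CA radius 2.3 A)."""

    n_residues: int
    rise: float = 1.5
    twist: float = 100.0  # degrees per residue
    radius: float = 2.3
    axis_origin: np.ndarray | tuple = (0.0, 0.0, 0.0)
    axis_direction: np.ndarray | tuple = (0.0, 0.0, 1.0)
    phase: float = 0.0  # degrees

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValidationError("helix needs >= 3 residues")
        if self.rise <= 0:
            raise ValidationError("rise must be > 0")
        if self.radius < 0:
            raise ValidationError("radius must be >= 0")
        self.axis_origin = np.asarray(self.axis_origin, dtype=float)
        d = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValidationError("axis_direction must be nonzero")
        self.axis_direction = d / norm


def _axis_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to axis (deterministic)."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def make_ideal_helix(spec: HelixSpec) -> np.ndarray:
    """Ordered C-alpha coordinates of an ideal helix, shape (n, 3)."""
    u, v = _axis_frame(spec.axis_direction)
    i = np.arange(spec.n_residues)
    ang = np.deg2rad(spec.phase + i * spec.twist)
    return (
        spec.axis_origin[None, :]
        + np.outer(i * spec.rise, spec.axis_direction)
        + spec.radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    )


def _ca_residue(chain: str, num: int, xyz: np.ndarray) -> Residue:
    ref = ResidueRef(chain, num, "", "A")
    return Residue(ref=ref, name="ALA",
                   atoms=[AtomRecord("CA", "C", np.asarray(xyz, float))])


def make_bundle_model(
    helices: list[tuple[str, HelixSpec]],
    dimer: bool = False,
    seed: int = 0,
    entry_id: str = "SYNTH-BUNDLE",
    start_number: int = 10,
    gap: int = 10,
) -> tuple[StructureModel, SegmentAnnotation, dict]:
    """C-alpha-only helix bundle with labelled segments.

    ``helices`` pairs a segment name with a HelixSpec; residues are
    numbered consecutively per helix with ``gap`` unnumbered positions
    between segments. ``dimer=True`` adds chain B as a 180-degree rotation
    about the global z axis through x=25 (a recorded C2 operator). Helix
    pairs closer than 1 A CA-CA trigger a geometry warning in the truth
    record rather than an exception.
    """
    if len(helices) < 2:
        raise ValidationError("bundle needs >= 2 helices")
    chain_a: list[Residue] = []
    ranges: dict[str, list[tuple[str, int, int]]] = {}
    coords_per_helix: list[np.ndarray] = []
    num = start_number
    for name, spec in helices:
        xyz = make_ideal_helix(spec)
        coords_per_helix.append(xyz)
        start = num
        for row in xyz:
            chain_a.append(_ca_residue("A", num, row))
            num += 1
        ranges.setdefault(name, []).append(("A", start, num - 1))
        num += gap

    clashes = []
    for i in range(len(coords_per_helix)):
        for j in range(i + 1, len(coords_per_helix)):
            a, b = coords_per_helix[i], coords_per_helix[j]
            d = np.sqrt(((a[:, None] - b[None, :]) ** 2).sum(-1)).min()
            if d < 1.0:
                clashes.append((helices[i][0], helices[j][0], float(d)))

    model = StructureModel(entry_id=entry_id, chains={"A": chain_a})
    c2_center = np.array([25.0, 0.0, 0.0])
    c2_rot = np.diag([-1.0, -1.0, 1.0])  # 180 deg about z axis through c2_center
    truth: dict = {
        "seed": seed,
        "segments": {k: v[:] for k, v in ranges.items()},
        "clashes": clashes,
        "dimer": dimer,
    }
    if dimer:
        chain_b = []
        for res in chain_a:
            xyz = c2_rot @ (res.atoms[0].position - c2_center) + c2_center
            chain_b.append(_ca_residue("B", res.ref.residue_number, xyz))
        model.chains["B"] = chain_b
        for name in list(ranges):
            ranges[name] = ranges[name] + [
                ("B", s, e) for _, s, e in ranges[name]
            ]
        model.assembly_symmetry = "C2"
        truth["c2_rotation"] = c2_rot.tolist()
        truth["c2_center"] = c2_center.tolist()
    annotation = SegmentAnnotation(ranges=ranges)
    truth["segments"] = {k: [list(t) for t in v] for k, v in ranges.items()}
    return model, annotation, truth


def rotation_about(axis: np.ndarray | tuple, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def apply_rigid(
    coords: np.ndarray,
    rotation: np.ndarray,
    translation: np.ndarray | tuple,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Rigidly transform (and optionally jitter) coordinates, recording the
    transform as planted truth for superposition tests."""
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3) or not np.allclose(
        rotation @ rotation.T, np.eye(3), atol=1e-8
    ) or not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-8):
        raise ValidationError("rotation must be proper orthonormal (det +1)")
    translation = np.asarray(translation, dtype=float)
    out = np.asarray(coords, float) @ rotation.T + translation
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    truth = {
        "rotation": rotation.tolist(),
        "translation": translation.tolist(),
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return out, truth


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def make_cavity_shell(
    void_radius: float,
    probe_radius: float = 1.4,
    atom_spacing: float = 1.0,
    opening_angle: float = 0.0,
    seed: int = 0,
    center: np.ndarray | tuple = (0.0, 0.0, 0.0),
    shell_radius: float | None = None,
    entry_id: str = "SYNTH-SHELL",
) -> tuple[StructureModel, dict]:
    """Spherical pseudo-atom shell sealing (opening 0) or venting an
    interior void of analytically known volume (4/3 pi r^3).

    Atoms sit at ``void_radius + vdW + probe`` from the centre so the open
    region inside reaches exactly ``void_radius`` — the planted volume is
    exact up to lattice discretisation. ``opening_angle`` > 0 removes the
    polar cap around +z of that half-angle*2, venting the void to bulk.
    A spacing too coarse for the probe to be excluded raises, checked
    against the blocked-sphere overlap condition.
    """
    if void_radius <= 0:
        raise ValidationError("void_radius must be > 0")
    if shell_radius is None:
        shell_radius = void_radius + DEFAULT_VDW + probe_radius
    if shell_radius <= void_radius + probe_radius:
        raise ValidationError("shell_radius must exceed void_radius + probe_radius")
    reach = DEFAULT_VDW + probe_radius
    if atom_spacing > 0.95 * reach:
        raise GeneratorError(
            f"atom_spacing {atom_spacing} too sparse to seal the shell "
            f"(needs <= {0.95 * reach:.2f} A for vdW+probe {reach:.2f} A)"
        )
    n_atoms = max(int(np.ceil(4 * np.pi * shell_radius**2 / atom_spacing**2)), 12)
    directions = _fibonacci_sphere(n_atoms)
    if opening_angle > 0:
        half = np.deg2rad(opening_angle / 2.0)
        directions = directions[directions[:, 2] < np.cos(half)]
    center = np.asarray(center, dtype=float)
    points = center + shell_radius * directions

    residues = [_ca_residue("S", i + 1, xyz) for i, xyz in enumerate(points)]
    model = StructureModel(entry_id=entry_id, chains={"S": residues})
    truth = {
        "void_radius": void_radius,
        "shell_radius": shell_radius,
        "opening_angle": opening_angle,
        "analytic_volume": 4.0 / 3.0 * np.pi * void_radius**3,
        "n_atoms": len(points),
        "center": center.tolist(),
        "sealed": opening_angle == 0.0,
        "seed": seed,
    }
    return model, truth


def make_chain_ligand(
    n_atoms: int,
    spacing: float = 1.5,
    bend_angle: float = 0.0,
    component_code: str = "LIG",
) -> tuple[LigandInstance, dict]:
    """Planar linear (or uniformly bent) pseudo-ligand chain.

    Each successive bond turns by ``bend_angle`` degrees in the xy plane;
    with bend 0 the chain is collinear and the maximal extent is exactly
    (n-1) * spacing.
    """
    if n_atoms < 2:
        raise ValidationError("chain ligand needs >= 2 atoms")
    pos = np.zeros((n_atoms, 3))
    direction = np.array([1.0, 0.0, 0.0])
    turn = rotation_about((0, 0, 1), bend_angle)
    for i in range(1, n_atoms):
        pos[i] = pos[i - 1] + spacing * direction
        direction = turn @ direction
    atoms = [
        AtomRecord(f"C{i + 1}", "C", pos[i], is_hetero=True) for i in range(n_atoms)
    ]
    lig = LigandInstance(component_code=component_code, chain_id="L",
                         residue_number=1, atoms=atoms)
    truth = {
        "n_atoms": n_atoms,
        "spacing": spacing,
        "bend_angle": bend_angle,
        "collinear_extent": (n_atoms - 1) * spacing if bend_angle == 0 else None,
    }
    return lig, truth


def simulate_variant_table(
    n_residues: int = 745,
    n_hotspots: int = 88,
    n_single: int = 144,
    n_records: int = 970,
    seed: int = 0,
    hotspot_residues: list[int] | None = None,
    single_residues: list[int] | None = None,
    nonsense_fraction: float = 0.0,
) -> tuple[str, dict]:
    """TSV variant table with a planted number of hotspot residues.

    Hotspot residues receive >= 2 distinct alternate amino acids, singles
    exactly 1; leftover record budget becomes duplicates of existing
    substitutions (same protein change reported twice), and an optional
    fraction of extra nonsense rows is appended on hotspot residues (these
    are excluded by the default missense filter, so planted counts hold).
    Defaults plant the study-scale catalogue: 970 records over 232
    affected residues, 88 of them hotspots.
    """
    if n_hotspots + n_single > n_residues:
        raise ValidationError("n_hotspots + n_single exceeds n_residues")
    rng = np.random.default_rng(seed)
    if hotspot_residues is None or single_residues is None:
        chosen = rng.choice(np.arange(1, n_residues + 1),
                            size=n_hotspots + n_single, replace=False)
        hotspot_residues = sorted(int(x) for x in chosen[:n_hotspots])
        single_residues = sorted(int(x) for x in chosen[n_hotspots:])
    else:
        if set(hotspot_residues) & set(single_residues):
            raise ValidationError("hotspot and single residue lists overlap")
        n_hotspots, n_single = len(hotspot_residues), len(single_residues)

    ref_aa = {
        r: AA_FOR_SAMPLING[rng.integers(len(AA_FOR_SAMPLING))]
        for r in [*hotspot_residues, *single_residues]
    }

    subs: list[tuple[int, str, str]] = []
    for r in hotspot_residues:
        pool = [a for a in AA_FOR_SAMPLING if a != ref_aa[r]]
        k = int(rng.integers(2, 5))
        for alt in rng.choice(pool, size=k, replace=False):
            subs.append((r, ref_aa[r], str(alt)))
    for r in single_residues:
        pool = [a for a in AA_FOR_SAMPLING if a != ref_aa[r]]
        subs.append((r, ref_aa[r], str(pool[rng.integers(len(pool))])))

    if len(subs) > n_records:
        raise ValidationError(
            f"n_records={n_records} too small for {len(subs)} distinct substitutions"
        )
    dup_idx = rng.integers(0, len(subs), size=n_records - len(subs))
    rows = subs + [subs[i] for i in dup_idx]
    order = rng.permutation(len(rows))
    lines = ["protein_change\tvariant_class\tsource"]
    for i in order:
        r, ref, alt = rows[i]
        lines.append(f"p.{ref}{r}{alt}\tmissense\tsynthetic")
    n_nonsense = int(round(nonsense_fraction * n_records))
    for _ in range(n_nonsense):
        r = hotspot_residues[rng.integers(len(hotspot_residues))]
        lines.append(f"p.{ref_aa[r]}{r}*\tnonsense\tsynthetic")
    truth = {
        "n_records_missense": n_records,
        "n_affected": n_hotspots + n_single,
        "n_hotspots": n_hotspots,
        "hotspot_residues": list(hotspot_residues),
        "single_residues": list(single_residues),
        "n_nonsense": n_nonsense,
        "seed": seed,
    }
    return "\n".join(lines) + "\n", truth


def simulate_mm_data(
    vmax: float = 193.0,
    km: float = 0.17,
    conc_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[KineticsDataset, dict]:
    """Michaelis-Menten rate data on a concentration grid (default: 10
    points log-spaced over 0.01-2 uM, the working range of the acyl-CoA
    stimulation assay) with optional additive Gaussian noise."""
    if conc_grid is None:
        conc_grid = np.geomspace(0.01, 2.0, 10)
    conc_grid = np.asarray(conc_grid, dtype=float)
    rates = mm_rate(conc_grid, vmax, km)
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rates = rates + rng.normal(0.0, noise_sd, size=rates.shape)
    data = KineticsDataset(substrate_conc=conc_grid, rate=rates)
    truth = {"vmax": vmax, "km": km, "noise_sd": noise_sd, "seed": seed,
             "n_points": len(conc_grid)}
    return data, truth


def simulate_melt_curve(
    tm: float = 55.0,
    slope: float = 2.0,
    baselines: tuple[float, float] = (0.80, 1.10),
    noise_sd: float = 0.0,
    seed: int = 0,
    grid_step: float = 0.5,
) -> tuple[MeltCurve, dict]:
    """Two-state sigmoid melt in the F350/F330 ratio over a 25-95 degC ramp.

    ``slope`` is the transition width parameter (degC); ``baselines`` are
    the folded/unfolded ratio plateaus; ``noise_sd`` is the relative sd of
    multiplicative Gaussian noise applied per channel. Equal baselines
    produce a flat, transition-free curve (error-path fixture).
    """
    if not 25.0 < tm < 95.0:
        raise ValidationError("tm must lie inside the 25-95 degC ramp")
    t = np.arange(25.0, 95.0 + grid_step / 2, grid_step)
    low, high = baselines
    ratio = low + (high - low) / (1.0 + np.exp(-(t - tm) / slope))
    f330 = np.full_like(t, 1000.0)
    f350 = ratio * f330
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f350 = f350 * (1 + rng.normal(0, noise_sd, size=t.shape))
        f330 = f330 * (1 + rng.normal(0, noise_sd, size=t.shape))
    curve = MeltCurve(temperature=t, f350=f350, f330=f330)
    truth = {"tm": tm, "slope": slope, "baselines": list(baselines),
             "noise_sd": noise_sd, "seed": seed, "grid_step": grid_step}
    return curve, truth
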