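"""Superposition of conformational states and inter-segment distance metrics.

An ABC transporter like ALDP cycles between cytosolic-facing (open),
substrate-bound and ATP-bound (closed) conformations; the gating motion is
well summarised by the distance between TM4 and TM6 near the membrane
boundary ("juxta-membrane"), which collapses from >20 A to <6 A over the
cycle. This module provides:

* a closed-form Kabsch least-squares rigid superposition;
* per-residue C-alpha displacement maps between two states after
  superposing on a reference window (default use: NBD core);
* configurable segment-to-segment distance measurements (min CA-CA over
  terminal windows, or a single configured residue pair);
* minimum heavy-atom distance between two residues (all-heavy or
  side-chain subsets);
* a state x spec distance table emitted as TSV.

Distances are intra-model, so the state series needs no cross-state
superposition; superposition is only used for displacement maps.

The default TM4-TM6 convention (min CA-CA between the 5 terminal residues
of each helix) is this package's own operationalisation; published figures
rarely state which atoms were measured, so treat absolute agreement as a
calibration exercise (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConditioningError,
    EmptySubsetError,
    PairingError,
    ResidueNotFoundError,
    ValidationError,
)
from .structure_model import (
    CaTrace,
    Residue,
    ResidueRef,
    SegmentAnnotation,
    StructureModel,
    select_ca,
)

Metric = Literal["min_ca_ca", "pair_ca_ca"]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference: x -> R x + t."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float
    paired_count: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid-body superposition (Kabsch, via SVD).

    Finds the proper rotation R and translation t minimising
    sum_i |R m_i + t - r_i|^2 over paired points; the reported RMSD is the
    post-transform value. Reflections are excluded by the determinant
    correction, so chirality is preserved.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise PairingError(
            f"paired (N, 3) arrays required, got {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise PairingError(f"need at least 3 paired points, got {n}")

    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    m = mobile - mc
    r = reference - rc

    h = m.T @ r
    u, s, vt = np.linalg.svd(h)
    # collinear point sets leave the rotation about the line undetermined
    scale = max(s[0], 1e-12)
    if s[1] / scale < 1e-8:
        raise ConditioningError(
            "point sets are (near-)collinear; superposition is ill-conditioned"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    diff = m @ rot.T - r
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, paired_count=n)


@dataclass
class DisplacementTable:
    """Per-residue |delta CA| between two superposed states."""

    entries: list[tuple[ResidueRef, float]]
    superposition: SuperpositionResult

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chain": ref.chain_id,
                    "residue_number": ref.residue_number,
                    "amino_acid": ref.amino_acid,
                    "displacement_angstrom": d,
                }
                for ref, d in self.entries
            ]
        )


def per_residue_displacement(
    state_a: StructureModel,
    state_b: StructureModel,
    chain_map: dict[str, str] | None = None,
    alignment_window: tuple[str, int, int] | None = None,
) -> DisplacementTable:
    """Superpose B onto A on an alignment window, then report |delta| per
    shared C-alpha.

    ``chain_map`` maps chains of A to chains of B (default: same id).
    ``alignment_window`` is (chain_of_A, start, end); default: all shared
    residues.
    """
    chain_map = chain_map or {c: c for c in state_a.chains}
    pairs: list[tuple[ResidueRef, np.ndarray, np.ndarray]] = []
    for ca_chain, cb_chain in chain_map.items():
        if ca_chain not in state_a.chains or cb_chain not in state_b.chains:
            continue
        trace_a = select_ca(state_a, ca_chain)
        trace_b = select_ca(state_b, cb_chain)
        b_index = {
            (ref.residue_number, ref.insertion_code): xyz
            for ref, xyz in zip(trace_b.refs, trace_b.coords)
        }
        for ref, xyz in zip(trace_a.refs, trace_a.coords):
            match = b_index.get((ref.residue_number, ref.insertion_code))
            if match is not None:
                pairs.append((ref, xyz, match))
    if not pairs:
        raise PairingError("no shared residues between the two states under the chain map")

    refs = [p[0] for p in pairs]
    a_xyz = np.array([p[1] for p in pairs])
    b_xyz = np.array([p[2] for p in pairs])

    if alignment_window is None:
        mask = np.ones(len(pairs), dtype=bool)
    else:
        w_chain, w_start, w_end = alignment_window
        mask = np.array(
            [r.chain_id == w_chain and w_start <= r.residue_number <= w_end for r in refs]
        )
        if not mask.any():
            raise PairingError(
                f"alignment window {alignment_window} contains no shared residues"
            )
    sup = kabsch_superpose(b_xyz[mask], a_xyz[mask])
    moved = sup.apply(b_xyz)
    disp = np.linalg.norm(moved - a_xyz, axis=1)
    return DisplacementTable(entries=list(zip(refs, disp.tolist())), superposition=sup)


@dataclass
class DistanceSpec:
    """One segment-pair distance to measure on every state.

    ``window_a``/``window_b`` restrict each segment to an inclusive residue
    interval; ``terminal`` instead takes the N highest-numbered residues of
    the segment (the cytosolic end for TM helices in this topology).
    For ``pair_ca_ca`` both windows must resolve to exactly one residue.
    """

    name: str
    segment_a: str
    segment_b: str
    metric: Metric = "min_ca_ca"
    window_a: tuple[int, int] | None = None
    window_b: tuple[int, int] | None = None
    terminal: int | None = None
    chain_a: str | None = None
    chain_b: str | None = None


@dataclass
class DistanceMeasurement:
    spec: DistanceSpec
    value: float
    pair: tuple[ResidueRef, ResidueRef] | None = None


def _window_cas(model: StructureModel, annotation: SegmentAnnotation, segment: str,
                window: tuple[int, int] | None, terminal: int | None,
                chain: str | None) -> list[tuple[ResidueRef, np.ndarray]]:
    residues = annotation.residues_in(model, segment, chain)
    if window is not None:
        lo, hi = window
        residues = [r for r in residues if lo <= r.ref.residue_number <= hi]
    cas = [(r.ref, r.ca.position) for r in residues if r.ca is not None]
    if terminal is not None and window is None:
        by_chain: dict[str, list[tuple[ResidueRef, np.ndarray]]] = {}
        for ref, xyz in cas:
            by_chain.setdefault(ref.chain_id, []).append((ref, xyz))
        cas = []
        for items in by_chain.values():
            items.sort(key=lambda t: (t[0].residue_number, t[0].insertion_code))
            cas.extend(items[-terminal:])
    if not cas:
        raise ValidationError(
            f"segment {segment} window {window} yields no C-alpha positions"
        )
    return cas


def segment_distance(
    model: StructureModel,
    annotation: SegmentAnnotation,
    spec: DistanceSpec,
) -> DistanceMeasurement:
    """Distance between two annotated segments under the spec's metric.

    ``min_ca_ca``: minimum over all cross pairs of C-alpha positions.
    ``pair_ca_ca``: the single configured residue pair.
    """
    cas_a = _window_cas(model, annotation, spec.segment_a, spec.window_a,
                        spec.terminal, spec.chain_a)
    cas_b = _window_cas(model, annotation, spec.segment_b, spec.window_b,
                        spec.terminal, spec.chain_b)
    if spec.metric == "pair_ca_ca":
        if len(cas_a) != 1 or len(cas_b) != 1:
            raise ValidationError(
                f"pair_ca_ca needs single-residue windows, got {len(cas_a)} x {len(cas_b)}"
            )
        (ra, xa), (rb, xb) = cas_a[0], cas_b[0]
        return DistanceMeasurement(spec, float(np.linalg.norm(xa - xb)), (ra, rb))
    if spec.metric != "min_ca_ca":
        raise ValidationError(f"unknown metric {spec.metric!r}")

    xa = np.array([c for _, c in cas_a])
    xb = np.array([c for _, c in cas_b])
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(int(np.argmin(d2)), d2.shape)
    return DistanceMeasurement(
        spec, float(np.sqrt(d2[i, j])), (cas_a[i][0], cas_b[j][0])
    )


def residue_pair_min_distance(
    model: StructureModel,
    res_a: tuple[str, int] | ResidueRef,
    res_b: tuple[str, int] | ResidueRef,
    atom_subset: Literal["all_heavy", "side_chain"] = "all_heavy",
) -> float:
    """Minimum pairwise heavy-atom distance between two residues.

    With ``side_chain`` only non-backbone heavy atoms count; a glycine then
    raises, rather than silently falling back to CA.
    """

    def resolve(r) -> Residue:
        if isinstance(r, ResidueRef):
            return model.residue(r.chain_id, r.residue_number, r.insertion_code)
        chain, num = r
        return model.residue(chain, num)

    ra, rb = resolve(res_a), resolve(res_b)
    atoms_a = ra.heavy_atoms(atom_subset)
    atoms_b = rb.heavy_atoms(atom_subset)
    if not atoms_a or not atoms_b:
        empty = ra.ref if not atoms_a else rb.ref
        raise EmptySubsetError(f"residue {empty} has no atoms in subset {atom_subset!r}")
    xa = np.array([a.position for a in atoms_a])
    xb = np.array([a.position for a in atoms_b])
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def state_series_report(
    models: Sequence[tuple[str, StructureModel]],
    annotation: SegmentAnnotation,
    specs: Sequence[DistanceSpec],
) -> pd.DataFrame:
    """Distance table over an ordered series of states.

    Returns a long-format frame with columns
    ``state, spec_name, value_angstrom`` (one row per state x spec), the
    shape written to TSV by the CLI.
    """
    rows = []
    for state_name, model in models:
        for spec in specs:
            m = segment_distance(model, annotation, spec)
            rows.append(
                {"state": state_name, "spec_name": spec.name, "value_angstrom": m.value}
            )
    return pd.DataFrame(rows)


def default_tm4_tm6_spec(terminal: int = 5) -> DistanceSpec:
    """The package's juxta-membrane gating convention: min CA-CA between the
    5 terminal (cytosolic-end) residues of TM4 and TM6 of the same protomer."""
    return DistanceSpec(
        name="tm4_tm6_juxtamembrane",
        segment_a="TM4",
        segment_b="TM6",
        metric="min_ca_ca",
        terminal=terminal,
        chain_a="A",
        chain_b="A",
    )
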