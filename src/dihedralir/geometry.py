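"""Idealized peptide backbone geometry and amide I transition dipoles.

Builds poly-peptide backbones (N, CA, C, O per residue) from per-residue
Ramachandran angles by sequential internal-coordinate (NeRF) placement, places
amide I transition dipoles on the carbonyl groups, and imports backbone
geometry from standard PDB files.

Conventions
-----------
* Angles are in degrees, distances in Angstrom.
* Residue indexing is 1-based (matching position names such as L12, A13).
* The peptide bond is planar: omega is fixed at 180 degrees.
* phi of the first residue has no geometric consequence (there is no
  preceding carbonyl); it is accepted but unmeasurable from the coordinates.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DihedralAngles",
    "ResidueGeometry",
    "TransitionDipole",
    "PeptideModel",
    "BondParams",
    "build_segment",
    "place_dipoles",
    "measure_dihedrals",
    "build_model",
    "from_pdb",
    "to_pdb",
    "DEFAULT_SITE_FREQUENCY",
    "DEFAULT_ISOTOPE_SHIFT",
]

#: Unlabelled amide I site frequency (cm^-1); the unlabelled band of the
#: peptide sits at ~1650 cm^-1.
DEFAULT_SITE_FREQUENCY = 1650.0

#: 13C18O isotope shift applied to labelled sites (cm^-1).  The double
#: substitution moves the label ~65 cm^-1 below the unlabelled band.
DEFAULT_ISOTOPE_SHIFT = -65.0


def _normalize_angle(a: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = float(a) % 360.0
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


@dataclass(frozen=True)
class DihedralAngles:
    """A (phi, psi) Ramachandran pair in degrees, normalized to (-180, 180]."""

    phi: float
    psi: float

    def __post_init__(self):
        if not (math.isfinite(self.phi) and math.isfinite(self.psi)):
            raise ValueError(f"non-finite dihedral angles ({self.phi}, {self.psi})")
        object.__setattr__(self, "phi", _normalize_angle(self.phi))
        object.__setattr__(self, "psi", _normalize_angle(self.psi))


# Canonical secondary-structure presets.
ALPHA_HELIX = DihedralAngles(phi=-57.0, psi=-47.0)
PARALLEL_BETA_STRAND = DihedralAngles(phi=-119.0, psi=113.0)


@dataclass(frozen=True)
class BondParams:
    """Ideal backbone bond lengths (A) and angles (deg) for construction."""

    n_ca: float = 1.46
    ca_c: float = 1.52
    c_n: float = 1.33
    c_o: float = 1.23
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    omega: float = 180.0


@dataclass
class ResidueGeometry:
    """Backbone atom positions of one residue (Angstrom 3-vectors)."""

    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray

    def atoms(self) -> dict:
        return {"N": self.n, "CA": self.ca, "C": self.c, "O": self.o}


@dataclass
class TransitionDipole:
    """An amide I transition dipole attached to a carbonyl group.

    ``magnitude`` is a dimensionless multiple of the reference amide I
    transition dipole; the physical scale enters only through the
    transition-dipole-coupling parameters.
    """

    origin: np.ndarray
    direction: np.ndarray
    magnitude: float = 1.0

    def __post_init__(self):
        norm = np.linalg.norm(self.direction)
        if norm == 0:
            raise ValueError("zero-length dipole direction")
        self.direction = np.asarray(self.direction, float) / norm
        self.origin = np.asarray(self.origin, float)

    def vector(self) -> np.ndarray:
        """Direction scaled by magnitude (reference-dipole units)."""
        return self.magnitude * self.direction


@dataclass
class PeptideModel:
    """A coupled amide I site model: geometry, dipoles, local frequencies.

    ``dihedrals[i]`` holds the (phi, psi) of residue i+1 (0-based list,
    1-based residue numbering); entries may be None for PDB chain termini
    where a dihedral is undefined.  ``chain_ids`` marks chain membership so
    that coupling assembly can distinguish intra- from inter-chain pairs.
    """

    geometry: list
    dipoles: list
    site_frequencies: np.ndarray
    label_mask: np.ndarray
    dihedrals: list
    chain_ids: list = None
    residue_ids: list = None

    def __post_init__(self):
        n = self.n_sites
        self.site_frequencies = np.asarray(self.site_frequencies, float)
        self.label_mask = np.asarray(self.label_mask, bool)
        if self.chain_ids is None:
            self.chain_ids = ["A"] * n
        if self.residue_ids is None:
            self.residue_ids = list(range(1, n + 1))
        for name, seq in [
            ("dipoles", self.dipoles),
            ("site_frequencies", self.site_frequencies),
            ("label_mask", self.label_mask),
            ("dihedrals", self.dihedrals),
            ("chain_ids", self.chain_ids),
            ("residue_ids", self.residue_ids),
        ]:
            if len(seq) != n:
                raise ValueError(f"{name} has length {len(seq)}, expected {n}")

    @property
    def n_sites(self) -> int:
        return len(self.geometry)

    def with_labels(self, sites_1based, shift: float = DEFAULT_ISOTOPE_SHIFT) -> "PeptideModel":
        """Return a copy with the named residues isotope-labelled.

        ``sites_1based`` are 1-based positions into this model's site list;
        labelled sites get ``shift`` (negative) added to their frequency.
        """
        if shift >= 0:
            raise ValueError("isotope shift must be negative (heavy label)")
        mask = self.label_mask.copy()
        freqs = self.site_frequencies.copy()
        for s in sites_1based:
            i = s - 1
            if not 0 <= i < self.n_sites:
                raise IndexError(f"label site {s} outside 1..{self.n_sites}")
            if not mask[i]:
                mask[i] = True
                freqs[i] += shift
        return replace(self, site_frequencies=freqs, label_mask=mask,
                       geometry=list(self.geometry), dipoles=list(self.dipoles),
                       dihedrals=list(self.dihedrals),
                       chain_ids=list(self.chain_ids),
                       residue_ids=list(self.residue_ids))

    def with_site_frequencies(self, freqs) -> "PeptideModel":
        freqs = np.asarray(freqs, float)
        if freqs.shape != (self.n_sites,):
            raise ValueError("frequency array shape mismatch")
        return replace(self, site_frequencies=freqs)


# ---------------------------------------------------------------------------
# internal-coordinate construction
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement: position x with |x-c|=bond, angle(b,c,x)=angle,
    dihedral(a,b,c,x)=dihedral (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return _normalize_angle(math.degrees(math.atan2(y, x)))


def build_segment(dihedrals, bond_params: BondParams = BondParams()) -> list:
    """Build an idealized backbone from per-residue (phi, psi) pairs.

    Returns one :class:`ResidueGeometry` per input dihedral pair, chained by
    planar (omega = 180) peptide bonds.  The carbonyl O of residue i is placed
    in the peptide plane anti to N(i+1); for the last residue a virtual next N
    defined by its psi fixes the O position, so psi is realized for every
    residue.
    """
    if len(dihedrals) < 1:
        raise ValueError("at least one residue required")
    dihs = []
    for idx, d in enumerate(dihedrals, start=1):
        if not isinstance(d, DihedralAngles):
            try:
                d = DihedralAngles(*d)
            except ValueError as exc:
                raise ValueError(f"residue {idx}: {exc}") from exc
        if not (math.isfinite(d.phi) and math.isfinite(d.psi)):
            raise ValueError(f"residue {idx}: non-finite dihedral angle")
        dihs.append(d)

    bp = bond_params
    # Seed frame for residue 1: N at origin, CA on +x, C in the xy-plane.
    n1 = np.zeros(3)
    ca1 = np.array([bp.n_ca, 0.0, 0.0])
    ang = math.radians(bp.ang_n_ca_c)
    c1 = ca1 + bp.ca_c * np.array([-math.cos(ang), math.sin(ang), 0.0])

    ns, cas, cs = [n1], [ca1], [c1]
    for i in range(len(dihs)):
        psi = dihs[i].psi
        # next N from psi (virtual for the last residue)
        n_next = _place_atom(ns[i], cas[i], cs[i], bp.c_n, bp.ang_ca_c_n, psi)
        if i + 1 < len(dihs):
            ns.append(n_next)
            ca_next = _place_atom(cas[i], cs[i], n_next, bp.n_ca, bp.ang_c_n_ca, bp.omega)
            cas.append(ca_next)
            phi = dihs[i + 1].phi
            c_next = _place_atom(cs[i], n_next, ca_next, bp.ca_c, bp.ang_n_ca_c, phi)
            cs.append(c_next)
        else:
            virtual_n = n_next
    residues = []
    for i in range(len(dihs)):
        nn = ns[i + 1] if i + 1 < len(dihs) else virtual_n
        # O anti to the next N across the sp2 carbon, in the peptide plane
        psi = dihs[i].psi
        o = _place_atom(ns[i], cas[i], cs[i], bp.c_o, bp.ang_ca_c_o,
                        _normalize_angle(psi + 180.0))
        residues.append(ResidueGeometry(n=ns[i], ca=cas[i], c=cs[i], o=o))
    return residues


def measure_dihedrals(geometry) -> list:
    """Measure (phi, psi) for each residue of a built backbone.

    phi of the first residue is undefined (returned as NaN); psi of the last
    residue is recovered from the O position (O is anti to the peptide-plane
    N, so psi = dihedral(N, CA, C, O) + 180).
    """
    out = []
    n = len(geometry)
    for i, res in enumerate(geometry):
        if i == 0:
            phi = float("nan")
        else:
            phi = dihedral_angle(geometry[i - 1].c, res.n, res.ca, res.c)
        if i + 1 < n:
            psi = dihedral_angle(res.n, res.ca, res.c, geometry[i + 1].n)
        else:
            psi = _normalize_angle(
                dihedral_angle(res.n, res.ca, res.c, res.o) + 180.0)
        out.append((phi, psi))
    return out


def validate_geometry(geometry, co_tol=0.05, cn_tol=0.05,
                      bond_params: BondParams = BondParams()) -> None:
    """Check C=O bond lengths and peptide-bond connectivity."""
    for i, res in enumerate(geometry, start=1):
        co = np.linalg.norm(res.o - res.c)
        if abs(co - bond_params.c_o) > co_tol:
            raise ValueError(f"residue {i}: C=O length {co:.3f} A out of range")
    for i in range(len(geometry) - 1):
        cn = np.linalg.norm(geometry[i + 1].n - geometry[i].c)
        if abs(cn - bond_params.c_n) > cn_tol:
            raise ValueError(
                f"residues {i + 1}-{i + 2}: C-N length {cn:.3f} A out of range")


# ---------------------------------------------------------------------------
# transition dipoles
# ---------------------------------------------------------------------------

def place_dipoles(geometry, tilt: float = 20.0, magnitude: float = 1.0,
                  origin_fraction: float = 0.5) -> list:
    """Place one transition dipole on each carbonyl.

    The dipole direction is the C->O axis rotated by ``tilt`` degrees within
    the sp2 (O=C-N) plane, toward the amide nitrogen of the next residue (for
    the chain terminus, away from CA, which lies on the opposite side of the
    same plane).  The origin sits on the C=O bond at ``origin_fraction`` of
    the way from C to O.
    """
    dipoles = []
    n = len(geometry)
    for i, res in enumerate(geometry):
        co = res.o - res.c
        norm = np.linalg.norm(co)
        if norm < 1e-6:
            raise ValueError(f"residue {i + 1}: degenerate C=O bond")
        axis = co / norm
        # in-plane reference pointing toward the next amide N
        if i + 1 < n:
            v = geometry[i + 1].n - res.c
        else:
            v = -(res.ca - res.c)
        u = v - np.dot(v, axis) * axis
        un = np.linalg.norm(u)
        if un < 1e-9:
            raise ValueError(f"residue {i + 1}: cannot define dipole plane")
        u /= un
        t = math.radians(tilt)
        direction = math.cos(t) * axis + math.sin(t) * u
        origin = res.c + origin_fraction * co
        dipoles.append(TransitionDipole(origin=origin, direction=direction,
                                        magnitude=magnitude))
    return dipoles


def build_model(dihedrals, site_frequency: float = DEFAULT_SITE_FREQUENCY,
                tilt: float = 20.0, magnitude: float = 1.0,
                bond_params: BondParams = BondParams(),
                chain_id: str = "A") -> PeptideModel:
    """Convenience: build geometry + dipoles + default frequencies."""
    dihs = [d if isinstance(d, DihedralAngles) else DihedralAngles(*d)
            for d in dihedrals]
    geom = build_segment(dihs, bond_params)
    dips = place_dipoles(geom, tilt=tilt, magnitude=magnitude)
    n = len(geom)
    return PeptideModel(
        geometry=geom, dipoles=dips,
        site_frequencies=np.full(n, site_frequency),
        label_mask=np.zeros(n, bool),
        dihedrals=dihs,
        chain_ids=[chain_id] * n,
    )


def transform_model(model: PeptideModel, rotation=None, translation=None) -> PeptideModel:
    """Apply a rigid-body transform (rotation then translation) to a model."""
    R = np.eye(3) if rotation is None else np.asarray(rotation, float)
    t = np.zeros(3) if translation is None else np.asarray(translation, float)
    geom = [ResidueGeometry(n=R @ r.n + t, ca=R @ r.ca + t,
                            c=R @ r.c + t, o=R @ r.o + t)
            for r in model.geometry]
    dips = [TransitionDipole(origin=R @ d.origin + t, direction=R @ d.direction,
                             magnitude=d.magnitude) for d in model.dipoles]
    return replace(model, geometry=geom, dipoles=dips)


def merge_models(models) -> PeptideModel:
    """Concatenate several chains into one multi-chain model.

    Chain identities are preserved (made unique if they collide) so that
    coupling assembly treats cross-chain neighbours by TDC, never the map.
    """
    geometry, dipoles, dihedrals, chains, resids = [], [], [], [], []
    freqs, mask = [], []
    seen = set()
    for k, m in enumerate(models):
        cid = m.chain_ids[0]
        if cid in seen:
            cid = f"{cid}{k}"
        seen.add(cid)
        geometry += list(m.geometry)
        dipoles += list(m.dipoles)
        dihedrals += list(m.dihedrals)
        chains += [cid] * m.n_sites
        resids += list(m.residue_ids)
        freqs += list(m.site_frequencies)
        mask += list(m.label_mask)
    return PeptideModel(geometry=geometry, dipoles=dipoles,
                        site_frequencies=np.array(freqs),
                        label_mask=np.array(mask, bool),
                        dihedrals=dihedrals, chain_ids=chains,
                        residue_ids=resids)


# ---------------------------------------------------------------------------
# PDB import / export
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C", "O")


def from_pdb(pdb_source, chain: str = "A", residue_range=None,
             tilt: float = 20.0, magnitude: float = 1.0) -> PeptideModel:
    """Build a PeptideModel from the backbone of a standard PDB file.

    ``pdb_source`` is a file path or a file-like object of PDB text.  Author
    (1-based) residue numbering is preserved in ``residue_ids``.  Only the
    first model of a multi-model file is used (a notice is logged).  Site
    frequencies default to :data:`DEFAULT_SITE_FREQUENCY` and no site is
    labelled.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    handle = pdb_source
    if isinstance(pdb_source, str) and "\n" in pdb_source:
        handle = io.StringIO(pdb_source)
    structure = parser.get_structure("model", handle)
    models = list(structure)
    if not models:
        raise ValueError("no models in PDB input")
    if len(models) > 1:
        logger.info("PDB input has %d models; using the first", len(models))
    mdl = models[0]
    if chain not in [c.id for c in mdl]:
        raise ValueError(f"chain {chain!r} not present in PDB input")
    ch = mdl[chain]
    residues = [r for r in ch if r.id[0] == " "]
    if residue_range is not None:
        lo, hi = residue_range
        residues = [r for r in residues if lo <= r.id[1] <= hi]
        got = {r.id[1] for r in residues}
        missing = [i for i in range(lo, hi + 1) if i not in got]
        if missing:
            raise ValueError(
                f"residues {missing} of requested range {lo}-{hi} absent "
                f"from chain {chain!r}")
    if not residues:
        raise ValueError(f"no residues selected from chain {chain!r}")
    bad = [r.id[1] for r in residues
           if any(a not in r for a in _BACKBONE)]
    if bad:
        raise ValueError(
            f"missing backbone atoms (need N, CA, C, O) in residues {bad}")
    geom = [ResidueGeometry(*(np.array(r[a].get_coord(), float)
                              for a in _BACKBONE)) for r in residues]
    dips = place_dipoles(geom, tilt=tilt, magnitude=magnitude)
    dih_pairs = measure_dihedrals(geom)
    dihedrals = []
    for phi, psi in dih_pairs:
        if math.isnan(phi):
            dihedrals.append(None)
        else:
            dihedrals.append(DihedralAngles(phi=phi, psi=psi))
    n = len(geom)
    return PeptideModel(
        geometry=geom, dipoles=dips,
        site_frequencies=np.full(n, DEFAULT_SITE_FREQUENCY),
        label_mask=np.zeros(n, bool),
        dihedrals=dihedrals,
        chain_ids=[chain] * n,
        residue_ids=[r.id[1] for r in residues],
    )


def to_pdb(model: PeptideModel, path=None) -> str:
    """Serialize backbone geometry as minimal PDB ATOM records.

    Returns the PDB text; also writes it to ``path`` when given.  Used for
    round-trip testing of the importer.
    """
    lines = []
    serial = 1
    for i, res in enumerate(model.geometry):
        resid = model.residue_ids[i]
        chain = str(model.chain_ids[i])[0]
        for name, pos in res.atoms().items():
            elem = name[0]
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} ALA {chain}{resid:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00"
                f"          {elem:>2s}")
            serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
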