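"""Idealised synthetic backbones and a deterministic geometry -> sequence code.

These fixtures stand in for experimental training data: parametric helices,
extended strands, hairpins, helix bundles and cyclic assemblies, plus a
"geometric code" that assigns each residue a letter from its burial quantile
(5 bins) and local pseudo-dihedral class (4 sectors) through a fixed
bijective 5x4 -> 20 lookup.  Burial dominates the code by construction, so
recovery-versus-burial analyses have a known ground-truth gradient.  The
code is a pure, rigid-motion-invariant function of coordinates, which makes
training, design and scoring testable end to end with no external data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .backbone import BackboneStructure, compute_virtual_cb, write_pdb
from .errors import GeometryError
from .features import burial_metric
from .seeds import substream

__all__ = [
    "SyntheticSpec",
    "CodeRule",
    "DEFAULT_CODE_RULE",
    "make_backbone",
    "make_cyclic_assembly",
    "geometric_code_labels",
    "make_dataset",
]

KINDS = ("helix", "strand", "two_helix_hairpin", "bundle", "cyclic_assembly")

# textbook alpha-helix Ca parameters
HELIX_RADIUS = 2.3  # Å
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue

# a gently twisted extended chain: Ca-Ca ~3.8 Å, pseudo-dihedral centred in
# a 90° sector (~-133°) so the per-structure curl never pushes windows
# across a sector boundary (a planar zig-zag would sit exactly on ±180°)
STRAND_RADIUS = 0.9
STRAND_RISE = 3.4
STRAND_TWIST = 140.0


@dataclasses.dataclass
class SyntheticSpec:
    """Recipe for one synthetic structure."""

    kind: str
    length: int = 20
    n_chains: int = 1  # symmetry order for cyclic assemblies
    radius: float = 8.0  # assembly radius in Å
    seed: int = 0
    jitter_std: float = 0.0  # Å of per-atom Gaussian jitter

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.length < 4:
            raise ValueError("length must be >= 4")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.jitter_std < 0:
            raise ValueError("jitter_std must be >= 0")


@dataclasses.dataclass
class CodeRule:
    """Burial-bin x geometry-class lookup onto the 20 amino acids (bijective)."""

    n_burial_bins: int = 5
    n_geom_classes: int = 4
    lookup: tuple = (
        ("L", "I", "V", "F"),  # most buried
        ("M", "A", "W", "Y"),
        ("G", "T", "S", "C"),
        ("P", "N", "Q", "H"),
        ("D", "E", "K", "R"),  # most exposed
    )

    def __post_init__(self):
        letters = [c for row in self.lookup for c in row]
        if sorted(letters) != sorted("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("lookup must cover the 20 amino acids exactly once")


DEFAULT_CODE_RULE = CodeRule()


def _helix_trace(length: int, radius: float, rise: float, twist_deg: float,
                 phase_deg: float = 0.0) -> np.ndarray:
    t = np.arange(length)
    ang = np.deg2rad(twist_deg) * t + np.deg2rad(phase_deg)
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), rise * t], axis=1)


def _curl(trace: np.ndarray, r_start: float, r_end: float,
          azimuth_deg: float) -> np.ndarray:
    """Curve a z-axial trace with curvature varying linearly along the chain.

    Regular straight helices and strands have two degeneracies that make
    burial ranks unstable: every interior residue sees the same environment,
    and positions i and n-1-i are mirror images.  A monotone curl (gentle at
    one end, tighter at the other) breaks both, giving each residue a
    distinct, stable burial, the way natural helices and sheets curve.  The
    axis curve is arc-length parametrised so Ca spacing is preserved to
    first order; `azimuth_deg` sets the curl plane.
    """
    rotated = _rot_z(trace, azimuth_deg)
    x, y, z = rotated[:, 0], rotated[:, 1], rotated[:, 2]
    z_span = max(z.max() - z.min(), 1e-9)
    s = z - z.min()
    kappa = (1.0 / r_start) + (1.0 / r_end - 1.0 / r_start) * s / z_span
    # tangent angle phi(s) = integral of kappa; closed form for linear kappa
    phi = s / r_start + (1.0 / r_end - 1.0 / r_start) * s * s / (2.0 * z_span)
    # axis position by cumulative integration on a fine grid
    grid = np.linspace(0.0, s.max(), 512)
    phi_g = grid / r_start + (1.0 / r_end - 1.0 / r_start) * grid ** 2 / (2.0 * z_span)
    ax_x = np.concatenate([[0.0], np.cumsum(np.diff(grid) * np.sin(phi_g[:-1]))])
    ax_z = np.concatenate([[0.0], np.cumsum(np.diff(grid) * np.cos(phi_g[:-1]))])
    cx = np.interp(s, grid, ax_x)
    cz = np.interp(s, grid, ax_z)
    # offset each residue along the local normal (cos phi, 0, -sin phi)
    bent = np.stack([cx + x * np.cos(phi), y, cz - x * np.sin(phi)], axis=1)
    bent[:, 2] += z.min()
    return _rot_z(bent, -azimuth_deg)


def _rot_x_180(xyz: np.ndarray) -> np.ndarray:
    return xyz * np.array([1.0, -1.0, -1.0])


def _rot_z(xyz: np.ndarray, deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    R = np.array([[np.cos(a), -np.sin(a), 0.0],
                  [np.sin(a), np.cos(a), 0.0],
                  [0.0, 0.0, 1.0]])
    return xyz @ R.T


def _atoms_from_ca_trace(ca: np.ndarray) -> np.ndarray:
    """Place N, C, O at ideal offsets in each residue's local Ca frame.

    Frames come from the Ca triplet (i-1, i, i+1); termini reuse the nearest
    interior frame.  Any self-consistent placement suffices here - the
    geometry only needs to be deterministic and chiral.
    """
    n = ca.shape[0]
    e1 = np.zeros_like(ca)
    e2 = np.zeros_like(ca)
    e3 = np.zeros_like(ca)
    for i in range(n):
        j = min(max(i, 1), n - 2)  # nearest interior residue
        fwd = ca[j + 1] - ca[j]
        back = ca[j - 1] - ca[j]
        a = fwd - back
        a = a / np.linalg.norm(a)
        b = np.cross(fwd, back)
        nb = np.linalg.norm(b)
        if nb < 1e-8:  # collinear triplet: pick any perpendicular
            b = np.cross(a, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(b) < 1e-8:
                b = np.cross(a, np.array([0.0, 1.0, 0.0]))
            nb = np.linalg.norm(b)
        b = b / nb
        e1[i], e3[i] = a, b
        e2[i] = np.cross(b, a)
    coords = np.zeros((n, 4, 3))
    coords[:, 1] = ca
    # ideal-ish bond lengths: N-Ca 1.458 Å, Ca-C 1.525 Å, C=O 1.23 Å
    d_n = -0.70 * e1 + 0.62 * e2 + 0.35 * e3
    d_c = 0.70 * e1 + 0.62 * e2 - 0.35 * e3
    coords[:, 0] = ca + 1.458 * d_n / np.linalg.norm(d_n, axis=1, keepdims=True)
    coords[:, 2] = ca + 1.525 * d_c / np.linalg.norm(d_c, axis=1, keepdims=True)
    d_o = 0.25 * e1 - 0.90 * e2 - 0.35 * e3
    coords[:, 3] = coords[:, 2] + 1.23 * d_o / np.linalg.norm(d_o, axis=1, keepdims=True)
    return coords


def _ca_trace_for(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Ca trace with per-structure shape variation (phase, gentle curvature).

    Shape variation, not coordinate jitter, is the main source of structural
    diversity: it changes each residue's burial smoothly and keeps the
    geometric-code labels stable.
    """
    L = spec.length
    # curls are self-similar across lengths: the total curl angle (not the
    # radius) is drawn, so a held-out length looks like a rescaled version
    # of its neighbors rather than a qualitatively different fold
    if spec.kind in ("helix", "cyclic_assembly"):
        tr = _helix_trace(L, HELIX_RADIUS, HELIX_RISE, HELIX_TWIST,
                          phase_deg=rng.uniform(0, 360))
        arc = (L - 1) * HELIX_RISE
        # cap the tight-end curvature so Ca spacing stays ideal (the helix
        # radius is 2.3 Å; offsets scale steps by 1 +- radius/bend_radius)
        k_mean = min(rng.uniform(0.8, 1.4) / arc, 1.0 / 21.0)
        return _curl(tr, 2.0 / k_mean, 2.0 / (3.0 * k_mean), rng.uniform(0, 360))
    if spec.kind == "strand":
        # curled tightly enough that the ends make tertiary contacts: a
        # straight extended chain has near-constant burial (its 8 nearest
        # residues are all sequence-local), which leaves nothing to design by
        tr = _helix_trace(L, STRAND_RADIUS, STRAND_RISE, STRAND_TWIST,
                          phase_deg=rng.uniform(0, 360))
        arc = (L - 1) * STRAND_RISE
        k_mean = rng.uniform(2.3, 3.1) / arc
        return _curl(tr, 2.0 / k_mean, 2.0 / (3.0 * k_mean), rng.uniform(0, 360))
    if spec.kind == "two_helix_hairpin":
        # arms splay apart: the inter-arm distance grows from the turn to the
        # free ends, so burial decreases monotonically along each arm instead
        # of being mirror-degenerate
        l1 = L // 2
        phase = rng.uniform(0, 360)  # one phase per structure: residues at
        # the arm junction keep a predictable relative geometry
        up = _helix_trace(l1, HELIX_RADIUS, HELIX_RISE, HELIX_TWIST,
                          phase_deg=phase)
        tilt = np.deg2rad(rng.uniform(8.0, 16.0))
        up = up @ np.array([[np.cos(tilt), 0, np.sin(tilt)],
                            [0, 1, 0],
                            [-np.sin(tilt), 0, np.cos(tilt)]]).T
        down = _rot_x_180(_helix_trace(L - l1, HELIX_RADIUS, HELIX_RISE, HELIX_TWIST,
                                       phase_deg=phase + 160.0))
        down = down + np.array([rng.uniform(8.0, 9.5), 0.0, up[-1, 2] + 4.5])
        return np.concatenate([up, down])
    if spec.kind == "bundle":
        # graded radial shells: each segment sits at a distinct distance from
        # the bundle axis, so segments occupy well-separated burial regimes
        per = [L // 3 + (1 if i < L % 3 else 0) for i in range(3)]
        base = rng.uniform(5.2, 6.2)
        shells = (0.8, 1.0, 1.6)
        phase = rng.uniform(0, 360)  # shared: keeps junction dihedrals regular
        segs = []
        for i, li in enumerate(per):
            seg = _helix_trace(li, HELIX_RADIUS, HELIX_RISE, HELIX_TWIST,
                               phase_deg=phase)
            if i % 2 == 1:  # alternate helix direction around the bundle
                seg = _rot_x_180(seg)
                seg = seg - np.array([0.0, 0.0, seg[:, 2].min()])
            seg = seg + np.array([base * shells[i], 0.0, 0.0])
            segs.append(_rot_z(seg, 120.0 * i))
        return np.concatenate(segs)
    raise ValueError(spec.kind)


def _assemble(coords_per_chain: list[np.ndarray]) -> BackboneStructure:
    chain_ids = [chr(ord("A") + i) for i in range(len(coords_per_chain))]
    coords = np.concatenate(coords_per_chain)
    n = coords.shape[0]
    chain_index = np.concatenate([
        np.full(c.shape[0], i, dtype=np.int64) for i, c in enumerate(coords_per_chain)])
    chain_pos = np.concatenate([
        np.arange(c.shape[0], dtype=np.int64) for c in coords_per_chain])
    residue_mask = np.ones(n, dtype=bool)
    return BackboneStructure(
        chain_ids=chain_ids,
        residue_numbers=[[str(i + 1) for i in range(c.shape[0])]
                         for c in coords_per_chain],
        coords=coords,
        cb=compute_virtual_cb(coords, residue_mask),
        atom_mask=np.ones((n, 4), dtype=bool),
        residue_mask=residue_mask,
        chain_index=chain_index,
        chain_pos=chain_pos,
    )


def make_backbone(spec: SyntheticSpec) -> BackboneStructure:
    """Build one synthetic structure; bit-identical for equal (spec, seed)."""
    geom_rng = substream(spec.seed, "geom", spec.kind, spec.length)
    ca = _ca_trace_for(spec, geom_rng)
    coords = _atoms_from_ca_trace(ca)
    if spec.kind == "cyclic_assembly" and spec.n_chains > 1:
        mono = _assemble([coords])
        out = make_cyclic_assembly(mono, spec.n_chains, spec.radius)
    else:
        out = _assemble([coords])
    if spec.jitter_std > 0:
        rng = substream(spec.seed, "jitter", spec.kind, spec.length)
        out.coords = out.coords + rng.normal(0.0, spec.jitter_std, out.coords.shape)
        out.cb = compute_virtual_cb(out.coords, out.residue_mask)
    return out


def make_cyclic_assembly(chain: BackboneStructure, n_sym: int,
                         radius: float) -> BackboneStructure:
    """n_sym radially offset copies related by 360/n_sym rotations about z."""
    if n_sym < 2:
        raise ValueError("n_sym must be >= 2")
    base = chain.coords + np.array([radius, 0.0, 0.0])
    copies = [_rot_z(base.reshape(-1, 3), 360.0 / n_sym * k).reshape(base.shape)
              for k in range(n_sym)]
    out = _assemble([c for c in copies])
    ca = out.coords[:, 1, :]
    L = chain.n_residues
    for a in range(n_sym):
        for b in range(a + 1, n_sym):
            d = np.linalg.norm(ca[a * L:(a + 1) * L, None, :]
                               - ca[None, b * L:(b + 1) * L, :], axis=-1)
            if d.min() < 2.0:
                raise GeometryError(
                    f"chains {a} and {b} clash (min Ca-Ca {d.min():.2f} Å)")
    return out


def _pseudo_dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


MAX_VIRTUAL_BOND = 5.0  # Å; a larger Ca-Ca step marks a chain discontinuity


def geometric_code_labels(structure: BackboneStructure,
                          rule: CodeRule = DEFAULT_CODE_RULE) -> str:
    """Deterministic letter per residue from burial quantile x dihedral class.

    Burial bins are rank-based within the structure.  The local class is the
    Ca(i-1, i, i+1, i+2) pseudo-dihedral in 90° sectors.  A valid window must
    lie within one chain and must not span a chain discontinuity (a Ca-Ca
    step above 5 Å, as at rigidly placed segment junctions): a dihedral
    across such a gap is not local geometry.  Termini and break-adjacent
    residues use the nearest valid window.
    """
    n = structure.n_residues
    if n < 5:
        raise ValueError("geometric code requires at least 5 residues")
    burial = burial_metric(structure)
    ranks = np.argsort(np.argsort(burial, kind="stable"), kind="stable")
    bins = (ranks * rule.n_burial_bins) // n
    ca = structure.coords[:, 1, :]
    letters = []
    for i in range(n):
        ci = structure.chain_index[i]
        members = np.nonzero(structure.chain_index == ci)[0]
        lo, hi = members[0], members[-1]
        if hi - lo + 1 < 4:
            raise ValueError("geometric code requires chains of >= 4 residues")
        starts = [w for w in range(lo, hi - 2)
                  if all(np.linalg.norm(ca[w + k + 1] - ca[w + k]) <= MAX_VIRTUAL_BOND
                         for k in range(3))]
        if not starts:  # no contiguous window: fall back to position clamp
            starts = [int(np.clip(i - 1, lo, hi - 3))]
        w = min(starts, key=lambda s_: (abs(s_ - (i - 1)), s_))
        ang = _pseudo_dihedral(ca[w], ca[w + 1], ca[w + 2], ca[w + 3])
        cls = int((ang + 180.0) // 90.0) % rule.n_geom_classes
        letters.append(rule.lookup[int(bins[i])][cls])
    return "".join(letters)


# mixed secondary-structure families; each entry is (kind, weight, lengths).
# Lengths are kept small so the five burial-quantile bins stay well separated
# in rank (few residues per bin) while every fold still has a clear
# core-to-surface gradient.
DEFAULT_MIX = (
    ("helix", 0.25, tuple(range(11, 20))),
    ("strand", 0.2, tuple(range(11, 20))),
    ("two_helix_hairpin", 0.25, tuple(range(15, 24))),
    ("bundle", 0.15, tuple(range(15, 25))),
    ("cyclic_assembly", 0.15, tuple(range(7, 13))),  # C2 dimers: 14-24 residues
)
# modest jitter: per-structure shape variation (curvature, phase) carries
# most within-cluster diversity; heavy jitter would randomise burial ranks
# near quantile boundaries and with them the code letters
DEFAULT_JITTER = 0.05


def make_dataset(n_structures: int, out_dir, rule: CodeRule = DEFAULT_CODE_RULE,
                 seed: int = 0, mix=DEFAULT_MIX, lengths=None,
                 jitter_std: float = DEFAULT_JITTER) -> list[str]:
    """Emit PDB files + sequences.fasta + clusters.tsv for training.

    `mix` entries are (kind, weight) or (kind, weight, lengths); a global
    `lengths` tuple overrides per-kind menus.  Cluster ids are (kind, length)
    so splits separate structural families.  Coordinates are rounded to PDB
    precision before labelling, so re-reading an emitted file and recomputing
    the code reproduces the emitted sequence exactly.  Returns record ids.
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = substream(seed, "dataset")
    entries = [(e[0], float(e[1]),
                tuple(lengths) if lengths is not None
                else (tuple(e[2]) if len(e) > 2 else (16, 20, 24)))
               for e in mix]
    weights = np.array([w for _, w, _ in entries])
    weights /= weights.sum()
    fasta_lines = []
    cluster_rows = []
    record_ids = []
    for i in range(n_structures):
        kind, _, kind_lengths = entries[int(rng.choice(len(entries), p=weights))]
        length = int(rng.choice(kind_lengths))
        structure = None
        for _attempt in range(50):  # rare: assembly copies may clash
            spec = SyntheticSpec(kind=kind, length=length,
                                 n_chains=2 if kind == "cyclic_assembly" else 1,
                                 radius=float(rng.uniform(7.0, 8.5)),
                                 seed=int(rng.integers(0, 2**31 - 1)),
                                 jitter_std=jitter_std)
            try:
                structure = make_backbone(spec)
                break
            except GeometryError:
                continue
        if structure is None:
            raise GeometryError(f"could not build a clash-free {kind} of length {length}")
        structure.coords = np.round(structure.coords, 3)  # PDB column precision
        structure.cb = compute_virtual_cb(structure.coords, structure.residue_mask)
        seq = geometric_code_labels(structure, rule)
        rid = f"s{i:04d}_{kind}_L{length}"
        write_pdb(structure, out_dir / f"{rid}.pdb", sequence=seq)
        fasta_lines += [f">{rid}", seq]
        cluster_rows.append(f"{rid}\t{kind}_L{length}")
        record_ids.append(rid)
    (out_dir / "sequences.fasta").write_text("\n".join(fasta_lines) + "\n")
    (out_dir / "clusters.tsv").write_text("\n".join(cluster_rows) + "\n")
    return record_ids
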