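"""Molecular graphs, MCS-Tanimoto similarity, and the structural-coherence test.

Molecules are element-labeled heavy-atom graphs with typed bonds (orders 1,
2, 3, or ``"ar"`` for aromatic).  The maximum common substructure (MCS) is
the largest common *connected* node-induced subgraph under strict element
and bond-order matching, found by branch-and-bound maximum-clique search on
the modular product graph with a greedy coloring bound; the Tanimoto score
counts heavy atoms:

    T(a, b) = |MCS| / (|a| + |b| - |MCS|)

The structural-coherence question — are the members of a hit set more alike
than chance? — is answered by comparing the median pairwise MCS-Tanimoto of
the hit set against the medians of many equally sized random draws from the
screening library.
"""

from __future__ import annotations

import dataclasses
import time
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MoleculeGraph",
    "parse_molecules",
    "write_sdf",
    "mcs_size",
    "mcs_tanimoto",
    "fingerprint_tanimoto",
    "pairwise_mcs_matrix",
    "quintuple_permutation_test",
    "SimilarityNull",
    "ChemError",
]

BondOrder = object  # 1 | 2 | 3 | "ar"


class ChemError(ValueError):
    pass


@dataclasses.dataclass
class MoleculeGraph:
    """Heavy-atom molecular graph: element symbols plus typed bonds."""

    name: str
    atoms: list[str]
    bonds: list[tuple[int, int, BondOrder]]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ChemError(f"{self.name}: bond ({i},{j}) index out of range")
            if i == j:
                raise ChemError(f"{self.name}: self-bond on atom {i}")
            if order not in (1, 2, 3, "ar"):
                raise ChemError(f"{self.name}: bad bond order {order!r}")
        self.multi_fragment = n > 0 and not self._connected()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbor_map(self) -> list[dict[int, BondOrder]]:
        nbr: list[dict[int, BondOrder]] = [dict() for _ in self.atoms]
        for i, j, order in self.bonds:
            nbr[i][j] = order
            nbr[j][i] = order
        return nbr

    def _connected(self) -> bool:
        if not self.atoms:
            return True
        nbr = self.neighbor_map()
        seen = {0}
        stack = [0]
        while stack:
            for j in nbr[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == len(self.atoms)


# ---------------------------------------------------------------------------
# parsing / writing (RDKit handles the file formats; aromatic flags are taken
# from the input — SDF bond type 4 or lowercase SMILES — with no re-perception)
# ---------------------------------------------------------------------------

_RD_ORDER = {"SINGLE": 1, "DOUBLE": 2, "TRIPLE": 3, "AROMATIC": "ar"}


def _from_rdkit(mol, name: str) -> MoleculeGraph:
    keep = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() != "H"]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [mol.GetAtomWithIdx(i).GetSymbol() for i in keep]
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            order = _RD_ORDER.get(b.GetBondType().name)
            if order is None:
                raise ChemError(f"{name}: unsupported bond type {b.GetBondType()}")
            bonds.append((remap[i], remap[j], order))
    return MoleculeGraph(name=name, atoms=atoms, bonds=bonds)


def parse_molecules(path: str | Path, format: str = "sdf") -> list[MoleculeGraph]:
    """Read molecules from an SDF or SMILES file into heavy-atom graphs.

    Unparsable records are skipped with a warning.  SMILES files carry one
    molecule per line, optionally followed by whitespace and a name.
    """
    from rdkit import Chem

    path = Path(path)
    out: list[MoleculeGraph] = []
    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        for idx, mol in enumerate(supplier):
            if mol is None:
                warnings.warn(f"skipping unparsable SDF record {idx} in {path}")
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{idx}"
            out.append(_from_rdkit(mol, name or f"mol{idx}"))
    elif format == "smiles":
        for idx, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            mol = Chem.MolFromSmiles(parts[0], sanitize=False)
            if mol is None:
                warnings.warn(f"skipping unparsable SMILES on line {idx + 1} of {path}")
                continue
            name = parts[1].strip() if len(parts) > 1 else f"mol{idx}"
            out.append(_from_rdkit(mol, name))
    else:
        raise ChemError(f"unknown molecule format {format!r}")
    return out


def write_sdf(mols: Sequence[MoleculeGraph], path: str | Path) -> None:
    """Write molecule graphs to an SDF (V2000) file via RDKit."""
    from rdkit import Chem

    rd_order = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                3: Chem.BondType.TRIPLE, "ar": Chem.BondType.AROMATIC}
    with open(path, "w") as fh:
        for m in mols:
            rw = Chem.RWMol()
            for el in m.atoms:
                atom = Chem.Atom(el)
                atom.SetNoImplicit(True)
                rw.AddAtom(atom)
            for i, j, order in m.bonds:
                rw.AddBond(i, j, rd_order[order])
                if order == "ar":
                    rw.GetAtomWithIdx(i).SetIsAromatic(True)
                    rw.GetAtomWithIdx(j).SetIsAromatic(True)
            mol = rw.GetMol()
            mol.SetProp("_Name", m.name)
            block = Chem.MolToMolBlock(mol, kekulize=False)
            fh.write(block)
            fh.write("$$$$\n")


# ---------------------------------------------------------------------------
# maximum common substructure
# ---------------------------------------------------------------------------


def _popcount(x: int) -> int:
    return x.bit_count()


def mcs_size(
    a: MoleculeGraph,
    b: MoleculeGraph,
    atom_limit: int = 60,
    time_budget: float = 5.0,
) -> tuple[int, bool]:
    """Size of the largest common connected induced subgraph.

    Returns ``(size, approximate)``; ``approximate`` is True when the time
    budget expired and the result is the best clique found so far (a lower
    bound).  Deterministic given the inputs.
    """
    na, nb = a.n_atoms, b.n_atoms
    if na == 0 or nb == 0:
        raise ChemError("molecules must be nonempty")
    if na > atom_limit or nb > atom_limit:
        raise ChemError(
            f"molecule above atom_limit={atom_limit}; use fingerprint_tanimoto"
        )
    nbr_a = a.neighbor_map()
    nbr_b = b.neighbor_map()

    # modular product vertices: element-compatible atom pairs
    verts = [(i, j) for i in range(na) for j in range(nb) if a.atoms[i] == b.atoms[j]]
    nv = len(verts)
    if nv == 0:
        return 0, False
    # order by product-graph degree (filled below); start with identity order
    comp = [0] * nv  # compatible (c- or d-edge) adjacency bitsets
    cadj = [0] * nv  # c-edge adjacency (both sides bonded, same order)
    for u in range(nv):
        i, j = verts[u]
        for v in range(u + 1, nv):
            k, l = verts[v]
            if i == k or j == l:
                continue
            oa = nbr_a[i].get(k)
            ob = nbr_b[j].get(l)
            if oa is None and ob is None:
                comp[u] |= 1 << v
                comp[v] |= 1 << u
            elif oa is not None and oa == ob:
                comp[u] |= 1 << v
                comp[v] |= 1 << u
                cadj[u] |= 1 << v
                cadj[v] |= 1 << u

    deadline = time.monotonic() + time_budget
    best = 1  # a single matched atom is always a common subgraph
    hard_cap = min(na, nb)
    approximate = False

    def color_bound(cand: int) -> int:
        # partition candidates into classes with no compatible pair inside:
        # at most one member of each class can join the clique
        classes = 0
        rest = cand
        while rest:
            classes += 1
            cls_ok = rest
            picked = 0
            while cls_ok:
                v = (cls_ok & -cls_ok).bit_length() - 1
                picked |= 1 << v
                # remove v and everything compatible with v from this class
                cls_ok &= ~((1 << v) | comp[v])
            rest &= ~picked
        return classes

    def expand(size: int, cand: int, reach: int) -> None:
        # cand: compatible with every clique member; reach: c-adjacent to the
        # clique (connectivity frontier).  Any vertex of cand may become
        # addable deeper down, so bounds are computed over cand, not
        # cand & reach.
        nonlocal best, approximate
        if time.monotonic() > deadline:
            approximate = True
            return
        addable = cand & reach
        while addable:
            if size + _popcount(cand) <= best:
                return
            if size + color_bound(cand) <= best:
                return
            v = (addable & -addable).bit_length() - 1
            if size + 1 > best:
                best = size + 1
            if best >= hard_cap:
                return
            expand(size + 1, cand & comp[v], reach | cadj[v])
            if approximate or best >= hard_cap:
                return
            cand &= ~(1 << v)
            addable = cand & reach

    mask_later = (1 << nv) - 1
    for u in range(nv):
        mask_later &= ~(1 << u)
        if best >= hard_cap or approximate:
            break
        if 1 + color_bound(comp[u] & mask_later) <= best:
            continue
        expand(1, comp[u] & mask_later, cadj[u])
    return best, approximate


def mcs_tanimoto(
    a: MoleculeGraph,
    b: MoleculeGraph,
    atom_limit: int = 60,
    time_budget: float = 5.0,
) -> float:
    """MCS Tanimoto score |MCS| / (|a| + |b| - |MCS|) over heavy atoms."""
    size, approx = mcs_size(a, b, atom_limit=atom_limit, time_budget=time_budget)
    if approx:
        warnings.warn(
            f"MCS time budget exceeded for ({a.name}, {b.name}); "
            "returning best bound found"
        )
    return size / (a.n_atoms + b.n_atoms - size)


# ---------------------------------------------------------------------------
# path fingerprints
# ---------------------------------------------------------------------------


def _path_set(mol: MoleculeGraph, max_path_length: int) -> frozenset:
    nbr = mol.neighbor_map()
    paths: set[tuple] = set()

    def walk(path_atoms: list[int], label: tuple) -> None:
        paths.add(min(label, label[::-1]))
        if (len(path_atoms) - 1) >= max_path_length:
            return
        last = path_atoms[-1]
        for nxt, order in nbr[last].items():
            if nxt in path_atoms:
                continue
            walk(path_atoms + [nxt], label + (str(order), mol.atoms[nxt]))

    for start in range(mol.n_atoms):
        walk([start], (mol.atoms[start],))
    return frozenset(paths)


def fingerprint_tanimoto(
    a: MoleculeGraph, b: MoleculeGraph, max_path_length: int = 5
) -> float:
    """Tanimoto of binary fingerprints of labeled simple paths up to
    ``max_path_length`` bonds."""
    fa = _path_set(a, max_path_length)
    fb = _path_set(b, max_path_length)
    union = len(fa | fb)
    return len(fa & fb) / union if union else 0.0


# ---------------------------------------------------------------------------
# random-quintuple permutation test
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SimilarityNull:
    """Observed hit-set coherence against the random-draw null."""

    observed_median: float
    null_medians: np.ndarray
    empirical_p: float
    percentile_95: float


def pairwise_mcs_matrix(
    mols: Sequence[MoleculeGraph],
    atom_limit: int = 60,
    time_budget: float = 5.0,
) -> np.ndarray:
    """Symmetric matrix of pairwise MCS Tanimoto scores (diagonal 1)."""
    n = len(mols)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = mcs_tanimoto(mols[i], mols[j], atom_limit, time_budget)
            mat[i, j] = mat[j, i] = s
    return mat


def _median_pairwise(mat: np.ndarray, idx: np.ndarray) -> float:
    sub = mat[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(np.median(sub[iu]))


def quintuple_permutation_test(
    hit_names: Sequence[str],
    library: Sequence[MoleculeGraph],
    n_permutations: int = 10000,
    seed: int = 0,
    pairwise: np.ndarray | None = None,
    atom_limit: int = 60,
    time_budget: float = 5.0,
) -> SimilarityNull:
    """Is the hit set structurally more coherent than random library draws?

    ``hit_names`` must name members of ``library``.  The observed statistic
    is the median pairwise MCS Tanimoto of the hit set; the null draws
    ``len(hit_names)`` library compounds without replacement per iteration.
    ``pairwise`` may supply a precomputed library similarity matrix.
    """
    if len(hit_names) < 2:
        raise ChemError("hit set must contain at least 2 molecules")
    if len(library) < 2 * len(hit_names):
        raise ChemError("library must be at least twice the hit-set size")
    name_to_idx = {m.name: i for i, m in enumerate(library)}
    missing = [n for n in hit_names if n not in name_to_idx]
    if missing:
        raise ChemError(f"hit molecules not in library: {missing}")
    if pairwise is None:
        pairwise = pairwise_mcs_matrix(library, atom_limit, time_budget)
    hit_idx = np.array([name_to_idx[n] for n in hit_names])
    observed = _median_pairwise(pairwise, hit_idx)
    rng = np.random.default_rng([int(seed) % (2**31), 11])
    k = len(hit_idx)
    null = np.empty(n_permutations)
    n_lib = len(library)
    for it in range(n_permutations):
        draw = rng.choice(n_lib, size=k, replace=False)
        null[it] = _median_pairwise(pairwise, draw)
    empirical_p = (1 + int(np.sum(null >= observed))) / (1 + n_permutations)
    return SimilarityNull(
        observed_median=observed,
        null_medians=null,
        empirical_p=empirical_p,
        percentile_95=float(np.percentile(null, 95)),
    )
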