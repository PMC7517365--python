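"""Protein contact networks from PDB coordinate files.

A protein contact network (PCN) is the minimal graph description of a folded
protein: one node per residue (located at its alpha-carbon) and an edge
wherever the Euclidean distance between two alpha-carbons falls inside a
[lower, upper] angstrom band, 4-8 A by default.  The lower bound removes the
trivial backbone-neighbour contacts (consecutive alpha-carbons sit ~3.8 A
apart), the upper bound reflects peptide-bond geometry (roughly two van der
Waals radii).  Residue and edge labels are deliberately dropped so that only
the topology remains.
"""

from __future__ import annotations

import io
import json
import logging
import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInputError, PDBParseError

logger = logging.getLogger(__name__)

_RESOLUTION_RE = re.compile(
    r"^REMARK\s+2\s+RESOLUTION\.\s+([0-9]+\.?[0-9]*)\s+ANGSTROM", re.MULTILINE
)
_EC_RE = re.compile(r"\bEC:\s*([0-9.,\s]+);")


@dataclass(frozen=True)
class ParsePolicy:
    """How ambiguous PDB content is resolved.

    first_chain_only
        If True, only the first chain of model 1 contributes residues;
        otherwise chains are concatenated in file order (whole-structure
        network, covering quaternary structure).
    """

    first_chain_only: bool = False


@dataclass
class ResidueChain:
    """Ordered alpha-carbon trace of one structure.

    coordinates is an (n, 3) float array in angstroms; resolution is the
    crystallographic resolution in angstroms (None when the header lacks
    it); ec_labels holds the distinct EC top-level digits annotated in the
    header (empty for non-enzymes).
    """

    identifier: str
    coordinates: np.ndarray
    resolution: float | None = None
    ec_labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n, 3) array")
        if self.coordinates.shape[0] == 0:
            raise ValueError("coordinates must be non-empty")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    @property
    def class_label(self) -> int:
        """EC top-level class in 1..6, or 7 for non-enzymes (no EC number)."""
        if len(self.ec_labels) == 1:
            return self.ec_labels[0]
        if not self.ec_labels:
            return 7
        raise ValueError(
            f"{self.identifier}: multiple EC classes {self.ec_labels}; "
            "filter such records before labelling"
        )


@dataclass(frozen=True)
class ContactNetwork:
    """Unweighted undirected residue-contact graph.

    Nodes are residue indices 0..node_count-1 in chain order; edges is a
    frozenset of (i, j) pairs with i < j.
    """

    node_count: int
    edges: frozenset

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if not (0 <= i < j < self.node_count):
                raise ValueError(f"invalid edge ({i}, {j}) for n={self.node_count}")

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def graph(self) -> nx.Graph:
        """The network as a networkx Graph (fresh copy)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.node_count))
        g.add_edges_from(self.edges)
        return g

    def adjacency(self) -> coo_matrix:
        """Sparse symmetric 0/1 adjacency matrix."""
        if not self.edges:
            return coo_matrix((self.node_count, self.node_count))
        rows, cols = zip(*self.edges)
        rows, cols = np.asarray(rows), np.asarray(cols)
        data = np.ones(2 * len(self.edges))
        return coo_matrix(
            (data, (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
            shape=(self.node_count, self.node_count),
        )

    def to_edge_list_text(self) -> str:
        """Plain-text edge list, one 'i j' pair per line, sorted."""
        lines = [f"{self.node_count}"]
        lines += [f"{i} {j}" for i, j in sorted(self.edges)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edge_list_text(cls, text: str) -> "ContactNetwork":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        n = int(lines[0])
        edges = frozenset(
            tuple(sorted(map(int, ln.split()))) for ln in lines[1:]
        )
        return cls(node_count=n, edges=edges)


def parse_ca_coordinates(
    pdb_text: str, policy: ParsePolicy | None = None, identifier: str = "structure"
) -> ResidueChain:
    """Extract the alpha-carbon trace from PDB-format text.

    Only the first model of a multi-model file is read and, for atoms with
    alternate locations, only the first location encountered is kept.
    Residues lacking a CA atom are skipped with a warning.  Resolution and
    EC annotations are taken from the header when present.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Atom import DisorderedAtom
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    policy = policy or ParsePolicy()
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(identifier, io.StringIO(pdb_text))

    models = list(structure.get_models())
    if not models:
        raise PDBParseError(f"{identifier}: no coordinate model found")
    first_model = models[0]

    coords: list[np.ndarray] = []
    for chain in first_model.get_chains():
        for residue in chain.get_residues():
            if residue.id[0].strip():  # skip HETATM / water records
                continue
            if "CA" not in residue:
                logger.warning(
                    "%s: residue %s%s lacks a CA atom; skipped",
                    identifier, chain.id, residue.id[1],
                )
                continue
            atom = residue["CA"]
            if isinstance(atom, DisorderedAtom):
                # child_dict preserves file order; keep the first altloc seen
                atom = next(iter(atom.child_dict.values()))
            coords.append(np.asarray(atom.coord, dtype=float))
        if policy.first_chain_only and coords:
            break

    if not coords:
        raise PDBParseError(f"{identifier}: no alpha-carbon atoms found")

    resolution = None
    m = _RESOLUTION_RE.search(pdb_text)
    if m:
        resolution = float(m.group(1))
    else:
        res = structure.header.get("resolution")
        if res is not None:
            resolution = float(res)

    ec_labels: list[int] = []
    for m in _EC_RE.finditer(pdb_text):
        for token in m.group(1).replace(",", " ").split():
            top = token.split(".")[0]
            if top.isdigit():
                digit = int(top)
                if digit not in ec_labels:
                    ec_labels.append(digit)

    return ResidueChain(
        identifier=identifier,
        coordinates=np.vstack(coords),
        resolution=resolution,
        ec_labels=ec_labels,
    )


def build_pcn(
    chain: ResidueChain, lower: float = 4.0, upper: float = 8.0
) -> ContactNetwork:
    """Build the contact network with edges at CA distances in [lower, upper].

    Both interval ends are closed.  Raises DegenerateInputError for chains
    shorter than two residues.
    """
    if len(chain) < 2:
        raise DegenerateInputError(
            f"{chain.identifier}: need >= 2 residues to build a contact network"
        )
    if not (0 <= lower < upper):
        raise ValueError(f"need 0 <= lower < upper, got [{lower}, {upper}]")
    dists = squareform(pdist(chain.coordinates))
    mask = (dists >= lower) & (dists <= upper)
    ii, jj = np.nonzero(np.triu(mask, k=1))
    return ContactNetwork(
        node_count=len(chain),
        edges=frozenset(zip(ii.tolist(), jj.tolist())),
    )


@dataclass
class FilterReport:
    """Per-rule discard counts from filter_dataset."""

    total: int = 0
    kept: int = 0
    missing_resolution: int = 0
    low_resolution: int = 0
    too_large: int = 0
    multiple_ec: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def filter_dataset(
    records: list[ResidueChain],
    max_resolution: float = 3.0,
    max_nodes: int = 1500,
    single_ec_only: bool = True,
) -> tuple[list[ResidueChain], FilterReport]:
    """Apply the structure-quality filters, preserving record order.

    Discards records with a missing resolution, resolution strictly above
    max_resolution (records at exactly the bound are retained), more than
    max_nodes residues, or more than one distinct EC top-level class.
    """
    report = FilterReport(total=len(records))
    kept: list[ResidueChain] = []
    for rec in records:
        if rec.resolution is None:
            report.missing_resolution += 1
            continue
        if rec.resolution > max_resolution:
            report.low_resolution += 1
            continue
        if len(rec) > max_nodes:
            report.too_large += 1
            continue
        if single_ec_only and len(rec.ec_labels) > 1:
            report.multiple_ec += 1
            continue
        kept.append(rec)
    report.kept = len(kept)
    return kept, report
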