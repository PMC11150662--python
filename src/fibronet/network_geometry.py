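"""Procedural spring networks: Poisson-disk/Voronoi parenchyma and hexagonal fixtures.

The extracellular matrix is a 2D network of Hookean springs. A non-uniform
network — Voronoi diagram of a Poisson-disk point set, mimicking the
semi-organized alveolar geometry of lung parenchyma — is the production
substrate; a regular honeycomb lattice serves as a deterministic fixture.
Networks are prestressed to a uniform strain (inflated parenchyma) and held
by constant boundary reaction forces so that they may contract as disease
remodels them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi

__all__ = [
    "DomainSpec",
    "SpringNetwork",
    "poisson_disk_sample",
    "build_voronoi_network",
    "hexagonal_network",
    "apply_prestress",
    "internal_forces",
    "compute_boundary_forces",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class DomainSpec:
    """Square sampling domain for network generation."""

    side: float = 15.0        # side length of the square domain
    radius: float = 1.0       # Poisson-disk exclusion radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side <= 0 or self.radius <= 0:
            raise ValueError("side and radius must be positive")
        if not self.radius < self.side / 4:
            raise ValueError("radius must be < side/4 (need interior cells)")


@dataclass
class SpringNetwork:
    """Mutable spring network state.

    Node and spring arrays are allocated once; rupture marks entries dead via
    the ``*_alive`` masks so that indices stay stable for agents and metrics.
    ``boundary_forces`` are the frozen external reaction forces (zero on
    interior nodes).
    """

    nodes: np.ndarray                 # (N, 2) coordinates
    springs: np.ndarray               # (M, 2) endpoint indices
    L0: np.ndarray                    # (M,) rest lengths
    A: np.ndarray                     # (M,) cross-sectional areas
    E: float = 1.0
    is_boundary: np.ndarray = None    # (N,) bool
    boundary_forces: np.ndarray = None  # (N, 2)
    node_alive: np.ndarray = None     # (N,) bool
    spring_alive: np.ndarray = None   # (M,) bool
    n_springs_initial: int = 0

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.springs = np.asarray(self.springs, dtype=np.intp).reshape(-1, 2)
        self.L0 = np.asarray(self.L0, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        n, m = len(self.nodes), len(self.springs)
        if self.is_boundary is None:
            self.is_boundary = np.zeros(n, dtype=bool)
        if self.boundary_forces is None:
            self.boundary_forces = np.zeros((n, 2))
        if self.node_alive is None:
            self.node_alive = np.ones(n, dtype=bool)
        if self.spring_alive is None:
            self.spring_alive = np.ones(m, dtype=bool)
        if not self.n_springs_initial:
            self.n_springs_initial = m
        self._validate()

    def _validate(self) -> None:
        m = len(self.springs)
        if len(self.L0) != m or len(self.A) != m:
            raise ValueError("spring attribute arrays disagree in length")
        if m and self.springs.max() >= len(self.nodes):
            raise ValueError("spring endpoint index out of range")
        if m and (self.springs[:, 0] == self.springs[:, 1]).any():
            raise ValueError("self-loop spring")
        key = np.sort(self.springs, axis=1)
        if m and len(np.unique(key, axis=0)) != m:
            raise ValueError("duplicate spring")

    # -- derived quantities -------------------------------------------------

    @property
    def n_live_nodes(self) -> int:
        return int(self.node_alive.sum())

    @property
    def n_live_springs(self) -> int:
        return int(self.spring_alive.sum())

    def lengths(self, coords: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if coords is None else coords
        d = x[self.springs[:, 1]] - x[self.springs[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def strains(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Per-spring engineering strain (nan for dead springs)."""
        eps = (self.lengths(coords) - self.L0) / self.L0
        eps[~self.spring_alive] = np.nan
        return eps

    def stiffnesses(self) -> np.ndarray:
        return self.E * self.A / self.L0

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=int)
        live = self.springs[self.spring_alive]
        np.add.at(deg, live.ravel(), 1)
        return deg

    def adjacency(self) -> list[list[tuple[int, int]]]:
        """Per-node list of (spring index, opposite node) over live springs."""
        adj: list[list[tuple[int, int]]] = [[] for _ in range(len(self.nodes))]
        for s in np.flatnonzero(self.spring_alive):
            i, j = self.springs[s]
            adj[i].append((int(s), int(j)))
            adj[j].append((int(s), int(i)))
        return adj

    def copy(self) -> "SpringNetwork":
        return SpringNetwork(
            nodes=self.nodes.copy(), springs=self.springs.copy(),
            L0=self.L0.copy(), A=self.A.copy(), E=self.E,
            is_boundary=self.is_boundary.copy(),
            boundary_forces=self.boundary_forces.copy(),
            node_alive=self.node_alive.copy(),
            spring_alive=self.spring_alive.copy(),
            n_springs_initial=self.n_springs_initial)


# ---------------------------------------------------------------------------
# Poisson-disk sampling (Bridson dart throwing)
# ---------------------------------------------------------------------------

def poisson_disk_sample(domain: DomainSpec, k: int = 30) -> np.ndarray:
    """Maximal Poisson-disk point set on the square domain.

    Bridson's algorithm: a background grid of cell size r/sqrt(2) makes
    neighbour queries O(1); each active sample spawns up to k candidates in
    the annulus [r, 2r) until none fits. All pairwise distances >= r and no
    empty disk of radius 2r fits fully inside the domain. Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(domain.seed)
    r, side = domain.radius, domain.side
    cell = r / np.sqrt(2.0)
    gw = int(np.ceil(side / cell))
    grid = -np.ones((gw, gw), dtype=np.intp)
    points: list[np.ndarray] = []

    def cell_of(p):
        return min(int(p[0] / cell), gw - 1), min(int(p[1] / cell), gw - 1)

    def fits(p):
        cx, cy = cell_of(p)
        for ix in range(max(cx - 2, 0), min(cx + 3, gw)):
            for iy in range(max(cy - 2, 0), min(cy + 3, gw)):
                q = grid[ix, iy]
                if q >= 0 and np.hypot(*(points[q] - p)) < r:
                    return False
        return True

    def insert(p):
        points.append(p)
        cx, cy = cell_of(p)
        grid[cx, cy] = len(points) - 1
        active.append(len(points) - 1)

    active: list[int] = []
    insert(rng.uniform(0.0, side, size=2))
    while active:
        pick = rng.integers(len(active))
        base = points[active[pick]]
        for _ in range(k):
            rho = rng.uniform(r, 2.0 * r)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            cand = base + rho * np.array([np.cos(theta), np.sin(theta)])
            if (0.0 <= cand[0] <= side and 0.0 <= cand[1] <= side and fits(cand)):
                insert(cand)
                break
        else:
            active.pop(pick)
    return np.array(points)


# ---------------------------------------------------------------------------
# Voronoi network construction
# ---------------------------------------------------------------------------

def _clip_segment(p0, p1, side):
    """Liang-Barsky clip of segment p0-p1 to [0,side]^2; None if outside."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for p, q in ((-d[0], p0[0] - 0.0), (d[0], side - p0[0]),
                 (-d[1], p0[1] - 0.0), (d[1], side - p0[1])):
        # inside condition: p*t <= q  (p<0: entering bound at t=q/p)
        if p == 0.0:
            if q < 0.0:
                return None
            continue
        t = q / p
        if p < 0.0:
            t0 = max(t0, t)
        else:
            t1 = min(t1, t)
    if t0 >= t1:
        return None
    return p0 + t0 * d, p0 + t1 * d


def build_voronoi_network(points: np.ndarray, domain: DomainSpec,
                          A0: float = 1.0, E: float = 1.0) -> SpringNetwork:
    """Spring network from the Voronoi diagram of a point set.

    Voronoi edges become springs with uniform area and modulus; edges
    crossing the square boundary are truncated there and the cut endpoint
    becomes a boundary node (well-defined hull for the reaction forces).
    Infinite ridges are extended far beyond the domain before clipping.
    Rest lengths are placeholders (current lengths) until prestressing.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 10:
        raise ValueError("need at least 10 generator points")
    side = domain.side
    vor = Voronoi(points)
    center = points.mean(axis=0)
    span = 4.0 * side
    tol = 1e-9 * side
    segs: list[tuple[np.ndarray, np.ndarray]] = []
    for (pi, pj), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        v0, v1 = ridge
        if v0 >= 0 and v1 >= 0:
            seg = _clip_segment(vor.vertices[v0], vor.vertices[v1], side)
        else:
            finite = vor.vertices[v1 if v0 < 0 else v0]
            # direction of the infinite ridge: perpendicular to the generator
            # pair, oriented away from the point-cloud center
            t = points[pj] - points[pi]
            t /= np.hypot(*t)
            n = np.array([-t[1], t[0]])
            mid = 0.5 * (points[pi] + points[pj])
            if np.dot(mid - center, n) < 0:
                n = -n
            seg = _clip_segment(finite, finite + span * n, side)
        if seg is not None and np.hypot(*(seg[1] - seg[0])) > tol:
            segs.append(seg)
    if not segs:
        raise ValueError("degenerate tessellation: no edges inside the domain")

    # deduplicate endpoints on a fine quantization grid
    quant = 1e-9 * side
    node_ids: dict[tuple[int, int], int] = {}
    nodes: list[np.ndarray] = []

    def nid(p):
        key = (int(round(p[0] / quant)), int(round(p[1] / quant)))
        if key not in node_ids:
            node_ids[key] = len(nodes)
            nodes.append(p)
        return node_ids[key]

    min_len = 1e-6 * side
    edge_set: set[tuple[int, int]] = set()
    edges: list[tuple[int, int]] = []
    for p0, p1 in segs:
        if np.hypot(*(p1 - p0)) < min_len:
            continue   # contracted: endpoints merge on the quantization grid
        i, j = nid(p0), nid(p1)
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in edge_set:
            continue
        edge_set.add(key)
        edges.append((i, j))

    coords = np.array(nodes)
    edges_arr = np.array(edges, dtype=np.intp)
    btol = 1e-7 * side
    on_edge = ((coords[:, 0] < btol) | (coords[:, 0] > side - btol)
               | (coords[:, 1] < btol) | (coords[:, 1] > side - btol))
    net = SpringNetwork(
        nodes=coords, springs=edges_arr,
        L0=np.hypot(*(coords[edges_arr[:, 1]] - coords[edges_arr[:, 0]]).T),
        A=np.full(len(edges_arr), float(A0)), E=float(E),
        is_boundary=on_edge)
    _drop_disconnected(net)
    return net


def _drop_disconnected(net: SpringNetwork) -> None:
    """Keep only the largest connected component (clipping can orphan corners)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    n = len(net.nodes)
    live = net.springs[net.spring_alive]
    adj = coo_matrix((np.ones(len(live)), (live[:, 0], live[:, 1])), shape=(n, n))
    ncomp, labels = connected_components(adj, directed=False)
    if ncomp <= 1:
        return
    deg = net.degrees()
    sizes = np.bincount(labels[deg > 0], minlength=ncomp)
    keep = sizes.argmax()
    dead_nodes = (labels != keep)
    net.node_alive[dead_nodes] = False
    dead_springs = dead_nodes[net.springs[:, 0]] | dead_nodes[net.springs[:, 1]]
    net.spring_alive[dead_springs] = False
    # isolated vertices with no springs at all
    net.node_alive[net.degrees() == 0] = False
    net.n_springs_initial = net.n_live_springs


# ---------------------------------------------------------------------------
# hexagonal fixture
# ---------------------------------------------------------------------------

def hexagonal_network(n_rings: int, edge_length: float = 1.0,
                      A0: float = 1.0, E: float = 1.0) -> SpringNetwork:
    """Regular honeycomb lattice of ``n_rings`` rings of hexagonal cells.

    n_rings=1 is a single hexagon (6 nodes, 6 springs). Boundary nodes are
    those of degree < 3. Deterministic fixture for mechanics tests.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    s = float(edge_length)
    # hexagonal cell centers in axial coordinates within the given ring count
    centers = []
    for q in range(-(n_rings - 1), n_rings):
        for rr in range(-(n_rings - 1), n_rings):
            if abs(q + rr) <= n_rings - 1:
                centers.append((q, rr))
    quant = 1e-9 * s
    node_ids: dict[tuple[int, int], int] = {}
    nodes: list[tuple[float, float]] = []
    edges_set: set[tuple[int, int]] = set()

    def nid(x, y):
        key = (int(round(x / quant)), int(round(y / quant)))
        if key not in node_ids:
            node_ids[key] = len(nodes)
            nodes.append((x, y))
        return node_ids[key]

    for q, rr in centers:
        cx = s * np.sqrt(3.0) * (q + rr / 2.0)
        cy = s * 1.5 * rr
        ids = []
        for kk in range(6):
            ang = np.pi / 6.0 + kk * np.pi / 3.0
            ids.append(nid(cx + s * np.cos(ang), cy + s * np.sin(ang)))
        for kk in range(6):
            i, j = ids[kk], ids[(kk + 1) % 6]
            edges_set.add((min(i, j), max(i, j)))

    coords = np.array(nodes)
    edges = np.array(sorted(edges_set), dtype=np.intp)
    net = SpringNetwork(
        nodes=coords, springs=edges,
        L0=np.hypot(*(coords[edges[:, 1]] - coords[edges[:, 0]]).T),
        A=np.full(len(edges), float(A0)), E=float(E))
    net.is_boundary = net.degrees() < 3
    return net


# ---------------------------------------------------------------------------
# prestress and boundary reaction forces
# ---------------------------------------------------------------------------

def apply_prestress(net: SpringNetwork, eps0: float) -> SpringNetwork:
    """Set rest lengths so every spring carries strain exactly eps0 in place."""
    if eps0 <= -1.0:
        raise ValueError("prestress strain must exceed -1")
    net.L0 = net.lengths() / (1.0 + eps0)
    return net


def internal_forces(net: SpringNetwork, coords: np.ndarray | None = None) -> np.ndarray:
    """Net internal spring force on every node (zero contribution from dead springs)."""
    x = net.nodes if coords is None else coords
    f = np.zeros_like(x)
    live = net.spring_alive
    i, j = net.springs[live, 0], net.springs[live, 1]
    d = x[j] - x[i]
    L = np.hypot(d[:, 0], d[:, 1])
    K = net.E * net.A[live] / net.L0[live]
    with np.errstate(invalid="ignore", divide="ignore"):
        u = d / L[:, None]
    u[L == 0] = 0.0
    T = (K * (L - net.L0[live]))[:, None] * u   # pull on i toward j when stretched
    np.add.at(f, i, T)
    np.add.at(f, j, -T)
    return f


def compute_boundary_forces(net: SpringNetwork) -> np.ndarray:
    """Freeze external forces on boundary nodes balancing the current state.

    Each boundary node receives minus its net internal spring force; interior
    nodes receive zero. When the interior is already at equilibrium the map
    sums to the zero vector (action-reaction) and the whole configuration is
    an equilibrium under the frozen forces.
    """
    f_int = internal_forces(net)
    forces = np.zeros_like(net.nodes)
    forces[net.is_boundary] = -f_int[net.is_boundary]
    net.boundary_forces = forces
    return forces


# ---------------------------------------------------------------------------
# plain-text serialization (exact round trip)
# ---------------------------------------------------------------------------

def save_network(net: SpringNetwork, path) -> None:
    """Write node and spring tables as plain text; floats at full precision."""
    buf = io.StringIO()
    buf.write("# fibronet network v1\n")
    buf.write(f"E\t{float(net.E)!r}\n")
    buf.write(f"n_springs_initial\t{net.n_springs_initial}\n")
    buf.write("[nodes]\tid\tx\ty\tis_boundary\tfx\tfy\talive\n")
    for i, (x, y) in enumerate(net.nodes):
        fx, fy = net.boundary_forces[i]
        buf.write(f"{i}\t{float(x)!r}\t{float(y)!r}\t{int(net.is_boundary[i])}"
                  f"\t{float(fx)!r}\t{float(fy)!r}\t{int(net.node_alive[i])}\n")
    buf.write("[springs]\tid\tnode_i\tnode_j\tL0\tA\talive\n")
    for s, (i, j) in enumerate(net.springs):
        buf.write(f"{s}\t{i}\t{j}\t{float(net.L0[s])!r}\t{float(net.A[s])!r}"
                  f"\t{int(net.spring_alive[s])}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def load_network(path) -> SpringNetwork:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("# fibronet network"):
        raise ValueError(f"not a fibronet network file: {path}")
    E = 1.0
    n_init = 0
    section = None
    nodes, bnd, forces, nalive = [], [], [], []
    springs, L0, A, salive = [], [], [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if parts[0] == "E":
            E = float(parts[1])
        elif parts[0] == "n_springs_initial":
            n_init = int(parts[1])
        elif parts[0] in ("[nodes]", "[springs]"):
            section = parts[0]
        elif section == "[nodes]":
            _, x, y, b, fx, fy, al = parts
            nodes.append((float(x), float(y)))
            bnd.append(bool(int(b)))
            forces.append((float(fx), float(fy)))
            nalive.append(bool(int(al)))
        elif section == "[springs]":
            _, i, j, l0, a, al = parts
            springs.append((int(i), int(j)))
            L0.append(float(l0))
            A.append(float(a))
            salive.append(bool(int(al)))
    return SpringNetwork(
        nodes=np.array(nodes), springs=np.array(springs, dtype=np.intp),
        L0=np.array(L0), A=np.array(A), E=E,
        is_boundary=np.array(bnd), boundary_forces=np.array(forces),
        node_alive=np.array(nalive), spring_alive=np.array(salive),
        n_springs_initial=n_init)
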