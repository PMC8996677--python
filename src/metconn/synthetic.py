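"""Ground-truthed synthetic data for every pipeline stage.

The study design this generator emulates: two groups of subjects (6 vs 12
family members, and 32 vs 33 in the replication arm), ~172 brain ROIs, and
ROI-level SUVR values treated as draws from a multivariate normal whose
sparse precision matrix encodes the metabolic network.  Hub nodes are
planted with degrees well above the background so the mean+1SD hub rule
has an unambiguous truth; group pairs are built by editing hub edges so
the lost / reconfigured taxonomy is known by construction.  For the ICA
stage, subject volumes are linear mixtures of compact spatial blobs
(super-Gaussian sources) plus Gaussian noise.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metconn.io_volumes import ROIAtlas, SUVRMatrix, Volume

#: default SUVR-like positive mean level added to sampled signals
SUVR_MEAN = 1.2
#: planted off-diagonal precision magnitudes (background edges)
EDGE_WEIGHT_RANGE = (0.1, 0.4)
#: magnitudes for hub-incident edges: the upper part of the range, so a
#: planted hub's degree is statistically identifiable at study-scale
#: sample sizes (a 0.1 precision entry is invisible at n ~ 50)
HUB_EDGE_WEIGHT_RANGE = (0.25, 0.4)
#: eigenvalue floor enforced by diagonal inflation
MIN_EIGENVALUE = 0.1


@dataclass
class PrecisionSpec:
    """A planted sparse precision matrix with designated hub nodes."""

    p: int
    theta: np.ndarray
    support: set  # frozenset-able set of (i, j) with i < j
    hub_nodes: tuple
    seed: int

    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.theta)

    def degrees(self) -> np.ndarray:
        k = np.zeros(self.p, dtype=int)
        for i, j in self.support:
            k[i] += 1
            k[j] += 1
        return k

    def density(self) -> float:
        return len(self.support) / (self.p * (self.p - 1) / 2)


@dataclass
class GroupPairSpec:
    """Two planted precisions differing by known hub edits."""

    spec_a: PrecisionSpec
    spec_b: PrecisionSpec
    planted_lost: tuple
    planted_reconfigured: tuple
    edit_log: list = field(default_factory=list)


def _assemble_theta(p, support, weights, rng) -> np.ndarray:
    """Build a symmetric theta from support and off-diagonal weights, then
    inflate the diagonal until the smallest eigenvalue reaches the floor.
    Diagonal inflation preserves the planted support exactly (unlike
    nearest-SPD projection)."""
    theta = np.eye(p)
    for (i, j), w in zip(support, weights):
        theta[i, j] = theta[j, i] = w
    for _ in range(60):
        w_min = np.linalg.eigvalsh(theta)[0]
        if w_min >= MIN_EIGENVALUE:
            return theta
        theta[np.diag_indices(p)] += (MIN_EIGENVALUE - w_min) + 0.05
    raise RuntimeError("failed to reach SPD after diagonal inflation")


def make_sparse_precision(
    p: int, density: float, n_hubs: int, seed: int, hub_nodes=None
) -> PrecisionSpec:
    """Plant a sparse SPD precision with ``n_hubs`` high-degree nodes.

    Hub nodes receive a degree at least 3x the median background degree;
    the remaining edge budget is scattered among non-hub pairs.  The
    realized density stays within 10% (relative) of the request.
    """
    if p < 4:
        raise ValueError("p must be >= 4")
    if not 0 <= density < 1:
        raise ValueError("density must be in [0, 1)")
    rng = np.random.default_rng(seed)
    max_edges = p * (p - 1) // 2
    m_total = int(round(density * max_edges))
    if m_total == 0:
        theta = np.eye(p)
        return PrecisionSpec(p=p, theta=theta, support=set(), hub_nodes=(), seed=seed)

    if hub_nodes is None:
        hub_nodes = tuple(sorted(rng.choice(p, size=n_hubs, replace=False))) if n_hubs else ()
    else:
        hub_nodes = tuple(sorted(hub_nodes))
        n_hubs = len(hub_nodes)
    non_hubs = [i for i in range(p) if i not in hub_nodes]

    edges: set = set()
    if n_hubs:
        # hub degree is a multiple of the scattered mean degree 2m/p; the
        # factor (5) keeps planted hubs far enough above the mean+1SD rule
        # to remain identifiable in networks re-estimated from study-scale
        # samples, while alternating edge signs keep SPD inflation mild
        d_hub = int(min(p - 1, max(4, 5 * np.ceil(2 * m_total / p))))
        if n_hubs * d_hub > 0.8 * m_total:
            d_hub = max(4, int(0.8 * m_total / n_hubs))
        if d_hub > p - 1:
            raise ValueError("density infeasible for requested hub count")
        for h in hub_nodes:
            partners = rng.choice([i for i in range(p) if i != h], size=d_hub, replace=False)
            for q in partners:
                edges.add((min(h, q), max(h, q)))
    # fill the remaining budget among non-hub pairs
    bg_pairs = [(i, j) for a, i in enumerate(non_hubs) for j in non_hubs[a + 1:]]
    rng.shuffle(bg_pairs)
    for pair in bg_pairs:
        if len(edges) >= m_total:
            break
        edges.add(pair)
    support = sorted(edges)
    signs = rng.choice([-1.0, 1.0], size=len(support))
    hub_set = set(hub_nodes)
    mags = np.array([
        rng.uniform(*(HUB_EDGE_WEIGHT_RANGE if (i in hub_set or j in hub_set)
                      else EDGE_WEIGHT_RANGE))
        for i, j in support
    ])
    theta = _assemble_theta(p, support, signs * mags, rng)
    spec = PrecisionSpec(p=p, theta=theta, support=set(support), hub_nodes=hub_nodes, seed=seed)
    if abs(spec.density() - density) > 0.1 * density + 1e-12:
        raise ValueError(
            f"realized density {spec.density():.4f} not within 10% of requested {density}"
        )
    return spec


def sample_suvr_matrix(
    spec: PrecisionSpec,
    n: int,
    group_label: str = "A",
    seed: int = 0,
    mean_level: float = SUVR_MEAN,
    subject_prefix: str | None = None,
) -> SUVRMatrix:
    """Draw n subjects from N(mean_level, inv(theta)) with age/sex covariates.

    The positive mean shift is cosmetic (covariance-invariant) but keeps
    values on an SUVR-like scale.  Age ~ N(50, 10), sex ~ Bernoulli(0.5).
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    cov = spec.covariance()
    L = np.linalg.cholesky(cov)
    X = mean_level + rng.standard_normal((n, spec.p)) @ L.T
    age = rng.normal(50.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n)
    prefix = subject_prefix or str(group_label)
    return SUVRMatrix(
        values=X,
        subject_ids=[f"{prefix}-{i+1:03d}" for i in range(n)],
        roi_labels=list(range(1, spec.p + 1)),
        group=np.array([group_label] * n),
        covariates=pd.DataFrame({"age": age, "sex": sex}),
    )


def make_group_pair(
    p: int,
    density: float,
    edits: dict | None,
    seed: int,
    n_lost: int | None = None,
    n_reconfigured: int | None = None,
    floor_degree: int = 2,
) -> GroupPairSpec:
    """Derive a target-group precision from a control one by hub edits.

    ``edits`` may carry ``n_lost``, ``n_reconfigured`` and ``floor_degree``
    (keyword arguments override).  Lost hubs keep only ``floor_degree`` of
    their control edges in the target truth; reconfigured nodes (chosen
    among control non-hubs) gain edges until their degree matches the
    control hubs'.  An empty edit description returns two identical specs.
    """
    edits = dict(edits or {})
    n_lost = edits.get("n_lost", 0) if n_lost is None else n_lost
    n_reconfigured = edits.get("n_reconfigured", 0) if n_reconfigured is None else n_reconfigured
    floor_degree = edits.get("floor_degree", floor_degree)

    rng = np.random.default_rng(seed)
    n_hubs = max(n_lost + 1, n_lost + n_reconfigured)  # keep >= 1 preserved hub when editing
    if n_lost == 0 and n_reconfigured == 0:
        spec_a = make_sparse_precision(p, density, 0, seed)
        spec_b = PrecisionSpec(
            p=p, theta=spec_a.theta.copy(), support=set(spec_a.support),
            hub_nodes=spec_a.hub_nodes, seed=seed,
        )
        return GroupPairSpec(spec_a=spec_a, spec_b=spec_b,
                             planted_lost=(), planted_reconfigured=(), edit_log=[])

    spec_a = make_sparse_precision(p, density, n_hubs, seed)
    hubs = list(spec_a.hub_nodes)
    lost = tuple(sorted(rng.choice(hubs, size=n_lost, replace=False))) if n_lost else ()
    # reconfigured plants must be unambiguous non-hubs in the control
    # truth: at or below the median degree, and not adjacent to a hub
    # (hub-incident edges are strong, and their partial-correlation
    # leakage inflates a neighbor's estimated degree in finite samples)
    deg0 = spec_a.degrees()
    med = np.median([deg0[i] for i in range(p) if i not in hubs])
    hub_adjacent = {q for i, j in spec_a.support if i in hubs or j in hubs for q in (i, j)}
    candidates = [
        i for i in range(p)
        if i not in hubs and deg0[i] <= med and i not in hub_adjacent
    ]
    if len(candidates) < n_reconfigured:
        candidates = [i for i in range(p) if i not in hubs and deg0[i] <= med]
    if len(candidates) < n_reconfigured:
        candidates = [i for i in range(p) if i not in hubs]
    reconf = (
        tuple(sorted(rng.choice(candidates, size=n_reconfigured, replace=False)))
        if n_reconfigured
        else ()
    )

    support_b = set(spec_a.support)
    edit_log: list = []
    deg_a = spec_a.degrees()
    for h in lost:
        incident = sorted(e for e in support_b if h in e)
        rng.shuffle(incident)
        for e in incident[floor_degree:]:
            support_b.discard(e)
            edit_log.append(("remove", *e))
    hub_degree = int(np.max(deg_a[list(spec_a.hub_nodes)])) if hubs else 6
    for r in reconf:
        current = sum(1 for e in support_b if r in e)
        partners = [i for i in range(p) if i != r and (min(i, r), max(i, r)) not in support_b]
        rng.shuffle(partners)
        for q in partners[: max(0, hub_degree - current)]:
            e = (min(r, q), max(r, q))
            support_b.add(e)
            edit_log.append(("add", *e))

    support_b = sorted(support_b)
    reconf_set = set(reconf)
    lost_set = set(lost)
    weights = []
    for i, j in support_b:
        if i in lost_set or j in lost_set:
            # the floor edges a lost hub keeps are ordinary background
            # edges in the target truth, not hub-strength ones
            weights.append(
                rng.uniform(EDGE_WEIGHT_RANGE[0], np.mean(EDGE_WEIGHT_RANGE))
                * rng.choice([-1.0, 1.0])
            )
        elif spec_a.theta[i, j] != 0 and (i, j) in spec_a.support:
            weights.append(spec_a.theta[i, j])
        else:
            rng_range = (
                HUB_EDGE_WEIGHT_RANGE
                if (i in reconf_set or j in reconf_set)
                else EDGE_WEIGHT_RANGE
            )
            weights.append(rng.uniform(*rng_range) * rng.choice([-1.0, 1.0]))
    theta_b = _assemble_theta(p, support_b, weights, rng)
    hubs_b = tuple(sorted(set(hubs) - set(lost)) + list(reconf))
    spec_b = PrecisionSpec(p=p, theta=theta_b, support=set(support_b),
                           hub_nodes=hubs_b, seed=seed)
    return GroupPairSpec(
        spec_a=spec_a, spec_b=spec_b,
        planted_lost=lost, planted_reconfigured=reconf, edit_log=edit_log,
    )


def _blob(shape, center, radius) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-d2 / (2.0 * radius**2))


def make_volume_dataset(
    dims: tuple[int, int, int],
    n_subjects: int,
    n_sources: int,
    noise_sd: float,
    seed: int,
    spacing=(2.0, 2.0, 2.0),
):
    """Subject volumes = mixing @ compact blob sources + Gaussian noise.

    Returns (volumes, mixing, source_maps, atlas).  Sources are spatially
    compact Gaussian blobs — sparse over the grid, hence super-Gaussian in
    value distribution, which is what Infomax-style ICA assumes.  The toy
    atlas labels each blob's core (source map > half max) 1..n_sources.
    """
    if n_sources < 2 or n_subjects <= n_sources:
        raise ValueError("need n_subjects > n_sources >= 2")
    dims = tuple(int(d) for d in dims)
    if min(dims) < 4 or np.prod(dims) < 8 * n_sources:
        raise ValueError("grid too small for requested sources")
    rng = np.random.default_rng(seed)
    radius = max(1.5, min(dims) / 6.0)
    centers = []
    attempts = 0
    while len(centers) < n_sources:
        c = [rng.uniform(0.15 * d, 0.85 * d) for d in dims]
        if all(sum((a - b) ** 2 for a, b in zip(c, c2)) > (2.5 * radius) ** 2 for c2 in centers):
            centers.append(c)
        attempts += 1
        if attempts > 2000:
            raise ValueError("grid too small to place well-separated sources")
    maps = np.stack([_blob(dims, c, radius).ravel() for c in centers])  # sources x voxels
    mixing = rng.normal(loc=2.0, scale=1.0, size=(n_subjects, n_sources))
    flat = mixing @ maps
    if noise_sd > 0:
        flat = flat + rng.normal(scale=noise_sd, size=flat.shape)
    volumes = [Volume(data=flat[s].reshape(dims), spacing=spacing) for s in range(n_subjects)]
    labels = np.zeros(dims, dtype=int)
    for c_idx in range(n_sources):
        core = maps[c_idx].reshape(dims) > 0.5
        labels[core & (labels == 0)] = c_idx + 1
    atlas = ROIAtlas(labels=labels, names={i + 1: f"source_{i+1}" for i in range(n_sources)})
    return volumes, mixing, maps, atlas
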