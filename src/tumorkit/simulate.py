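"""Seeded synthetic-data generators for every analysis stage.

Each generator emulates the statistical structure one pipeline stage
assumes — a clonal tree sampled binomially at realistic depths, UMI read
families with per-base substitution error, regulator-driven expression
shifts over Gaussian noise, an RPPA-like cohort matrix, and a tissue with
a collagen rim and a planted intensity-versus-distance gradient — so the
whole pipeline is testable without any controlled-access download. All
randomness flows from the ``SimParams.seed``; identical parameters yield
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ctdna import ReadFamily
from .regulon import RegulonNetwork
from .spatial import ECMMask, X_COL, Y_COL

__all__ = [
    "SimParams",
    "ClonalTree",
    "example_tree",
    "simulate_clonal_biopsies",
    "simulate_umi_reads",
    "make_regulon",
    "simulate_regulator_expression",
    "active_sample_ids",
    "simulate_rppa_cohort",
    "simulate_spatial_tissue",
    "simulate_additive_distances",
    "REF_WINDOW",
    "MUTANT_POSITION",
    "MUTANT_BASE",
]

#: reference site window used by the UMI-read generator; the monitored
#: mutation sits at ``MUTANT_POSITION`` with alternate allele ``MUTANT_BASE``.
REF_WINDOW = "ACGTAGCTA"
MUTANT_POSITION = 4
MUTANT_BASE = "G"

_OTHER = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


@dataclass(frozen=True)
class SimParams:
    """Shared simulation parameters.

    depth_mean: mean sequencing depth (reads) for biopsy variant sampling.
    error_rate: per-base substitution probability of raw reads.
    n_families / family_size_dist: UMI family count and size distribution,
        ("geometric", mean) or ("constant", size); geometric with mean 5
        approximates observed family-size decay.
    effect_size: expression shift (in noise-SD units times noise_sd) applied
        to targets of active regulators.
    noise_sd: SD of baseline Gaussian expression noise.
    gradient_slope: planted intensity decay per um of distance to the ECM rim.
    """

    seed: int = 0
    depth_mean: float = 1000.0
    error_rate: float = 1e-3
    n_families: int = 5000
    family_size_dist: tuple[str, float] = ("geometric", 5.0)
    effect_size: float = 3.0
    noise_sd: float = 1.0
    gradient_slope: float = 5.0
    n_samples: int = 30
    n_cells: int = 3000
    baseline_intensity: float = 500.0
    intensity_noise_sd: float = 50.0
    nest_radius_um: float = 100.0
    rim_width_um: float = 10.0
    pixel_size_um: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be a probability")
        for name in ("depth_mean", "n_families", "noise_sd", "n_samples", "n_cells"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        kind, value = self.family_size_dist
        if kind not in ("geometric", "constant") or value <= 0:
            raise ValueError(f"unsupported family size distribution {self.family_size_dist!r}")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for one simulation stream."""
        return np.random.default_rng((int(self.seed), int(stream)))


@dataclass(frozen=True)
class ClonalTree:
    """Clone phylogeny with per-branch mutation loads and biopsy assignments.

    ``parent`` maps each clone to its parent (None for the germline root);
    ``branch_mutations`` counts mutations acquired on the branch into each
    clone; ``sample_map`` assigns every biopsy to the clone it samples;
    ``purity`` is the tumor-cell fraction of each biopsy.
    """

    parent: Mapping[str, str | None]
    branch_mutations: Mapping[str, int]
    sample_map: Mapping[str, str]
    purity: Mapping[str, float]

    def __post_init__(self):
        roots = [c for c, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        nodes = set(self.parent)
        for c, p in self.parent.items():
            if p is not None and p not in nodes:
                raise ValueError(f"clone {c!r} has unknown parent {p!r}")
        for c in nodes:
            seen = set()
            cur: str | None = c
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle through clone {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]
        for c, k in self.branch_mutations.items():
            if c not in nodes:
                raise ValueError(f"branch mutations on unknown clone {c!r}")
            if k < 0:
                raise ValueError("branch mutation counts must be >= 0")
        for s, c in self.sample_map.items():
            if c not in nodes:
                raise ValueError(f"biopsy {s!r} maps to unknown clone {c!r}")
        for s, p in self.purity.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"purity of {s!r} outside [0, 1]")
        missing = set(self.sample_map) - set(self.purity)
        if missing:
            raise ValueError(f"no purity for biopsies {sorted(missing)}")

    @property
    def root(self) -> str:
        return next(c for c, p in self.parent.items() if p is None)

    def path_to_root(self, clone: str) -> list[str]:
        path = []
        cur: str | None = clone
        while cur is not None:
            path.append(cur)
            cur = self.parent[cur]
        return path


def example_tree(purity: float = 0.6) -> ClonalTree:
    """A five-biopsy clonal structure: truncal, metastatic-shared and
    private branches, the shape typical of a primary with serial metastases."""
    return ClonalTree(
        parent={
            "germline": None,
            "trunk": "germline",
            "met_ancestor": "trunk",
            "PT_clone": "trunk",
            "Bx1_clone": "met_ancestor",
            "Bx2_clone": "met_ancestor",
            "Bx34_clone": "trunk",
            "Bx3_clone": "Bx34_clone",
            "Bx4_clone": "Bx34_clone",
        },
        branch_mutations={
            "germline": 0,
            "trunk": 60,
            "met_ancestor": 30,
            "PT_clone": 25,
            "Bx1_clone": 20,
            "Bx2_clone": 20,
            "Bx34_clone": 15,
            "Bx3_clone": 15,
            "Bx4_clone": 15,
        },
        sample_map={
            "PT": "PT_clone",
            "Bx1": "Bx1_clone",
            "Bx2": "Bx2_clone",
            "Bx3": "Bx3_clone",
            "Bx4": "Bx4_clone",
        },
        purity={s: purity for s in ("PT", "Bx1", "Bx2", "Bx3", "Bx4")},
    )


def _branch_variants(tree: ClonalTree) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    counter = 0
    for clone in sorted(tree.parent):
        k = int(tree.branch_mutations.get(clone, 0))
        out[clone] = [f"m{counter + i:05d}" for i in range(k)]
        counter += k
    return out


def simulate_clonal_biopsies(tree: ClonalTree, params: SimParams) -> pd.DataFrame:
    """Sample per-biopsy variant observations from a clonal tree.

    A clone carries every mutation assigned to the branches on its path to
    the germline root. Per biopsy and variant, depth ~ Poisson(depth_mean)
    (floored at 1) and supporting reads ~ Binomial(depth, purity x 0.5 x
    presence) — heterozygous, copy-number neutral. The caller-emulation
    flag marks a variant called iff it has >= 3 supporting reads and
    VAF >= 5%, mirroring the downstream variant filter.

    Returns a table with one row per (sample, variant).
    """
    if params.depth_mean < 30:
        raise ValueError("depth_mean below 30 gives uninterpretable caller emulation")
    rng = params.rng(stream=1)
    variants_by_clone = _branch_variants(tree)
    all_variants = [v for clone in sorted(variants_by_clone) for v in variants_by_clone[clone]]
    rows = []
    for sample in sorted(tree.sample_map):
        clone = tree.sample_map[sample]
        carried = {
            v for c in tree.path_to_root(clone) for v in variants_by_clone.get(c, [])
        }
        purity = tree.purity[sample]
        for variant in all_variants:
            presence = 1.0 if variant in carried else 0.0
            depth = max(int(rng.poisson(params.depth_mean)), 1)
            p = purity * 0.5 * presence
            alt = int(rng.binomial(depth, p)) if p > 0 else 0
            vaf = alt / depth
            rows.append(
                {
                    "sample_id": sample,
                    "variant_id": variant,
                    "vaf": vaf,
                    "depth": depth,
                    "called": bool(alt >= 3 and vaf >= 0.05),
                    "supporting_reads": alt,
                }
            )
    return pd.DataFrame(rows)


def true_branch_category(tree: ClonalTree) -> pd.Series:
    """Ground-truth ubiquitous/shared/private label per simulated variant."""
    variants_by_clone = _branch_variants(tree)
    carried_by_sample = {
        s: {
            v
            for c in tree.path_to_root(tree.sample_map[s])
            for v in variants_by_clone.get(c, [])
        }
        for s in tree.sample_map
    }
    n = len(carried_by_sample)
    labels = {}
    for clone, variants in variants_by_clone.items():
        for v in variants:
            k = sum(v in carried for carried in carried_by_sample.values())
            if k == 0:
                continue
            labels[v] = "ubiquitous" if k == n else ("shared" if k >= 2 else "private")
    return pd.Series(labels, name="category")


def _family_sizes(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    kind, value = params.family_size_dist
    if kind == "constant":
        return np.full(params.n_families, int(value))
    return rng.geometric(1.0 / value, size=params.n_families)


def simulate_umi_reads(true_vaf: float, params: SimParams) -> list[ReadFamily]:
    """Generate UMI read families over the reference site window.

    Each family draws a true allele (mutant with probability ``true_vaf``),
    then emits ``family_size`` reads, each base independently substituted
    to a uniform other base with probability ``error_rate``. Indels and
    quality strings are not modeled.
    """
    if not 0.0 <= true_vaf <= 1.0:
        raise ValueError("true_vaf must be in [0, 1]")
    rng = params.rng(stream=2)
    sizes = _family_sizes(params, rng)
    mutant = rng.random(params.n_families) < true_vaf
    template_ref = list(REF_WINDOW)
    template_mut = list(REF_WINDOW)
    template_mut[MUTANT_POSITION] = MUTANT_BASE
    families = []
    for i, (size, is_mut) in enumerate(zip(sizes, mutant)):
        template = template_mut if is_mut else template_ref
        reads = []
        for _ in range(int(size)):
            bases = list(template)
            if params.error_rate > 0:
                hits = np.nonzero(rng.random(len(bases)) < params.error_rate)[0]
                for pos in hits:
                    bases[pos] = _OTHER[bases[pos]][rng.integers(3)]
            reads.append("".join(bases))
        families.append(
            ReadFamily(umi=f"f{i:06d}", site_window=REF_WINDOW, reads=tuple(reads))
        )
    return families


def example_bait_panel() -> pd.DataFrame:
    """Designed bait panel fixture: 55 selected SNVs, two QC-discarded.

    Mirrors the accounting of a personalized panel where 55 mutations pass
    the design filters but the oligonucleotides for two genes are later
    discarded for inconsistent coverage and high error rates, leaving 53
    monitored sites.
    """
    rows = []
    flagged = {17: "INVS", 38: "LILRA3"}
    for i in range(55):
        gene = flagged.get(i, f"GENE{i:02d}")
        rows.append(
            {
                "variant_id": f"{gene}_v{i:02d}",
                "gene": gene,
                "tumor_vaf": 0.10 + 0.005 * (i % 10),
                "normal_vaf": 0.0,
                "tumor_depth": 120,
                "normal_depth": 60,
                "qc_flag": "inconsistent coverage" if i in flagged else "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regulon fixtures
# ---------------------------------------------------------------------------

def make_regulon(
    n_regulators: int = 50,
    targets_per_regulator: int = 20,
    frac_negative: float = 0.3,
    seed: int = 0,
) -> RegulonNetwork:
    """Random regulon network with disjoint per-regulator target sets."""
    rng = np.random.default_rng((int(seed), 3))
    rows = []
    for r in range(n_regulators):
        reg = f"R{r:03d}"
        for t in range(targets_per_regulator):
            target = f"T{r:03d}_{t:03d}"
            sign = -1 if rng.random() < frac_negative else 1
            rows.append({"regulator": reg, "target": target, "sign": sign})
    return RegulonNetwork(edges=pd.DataFrame(rows))


def active_sample_ids(params: SimParams) -> list[str]:
    """Samples carrying the planted regulator effect.

    The activity scoring signature subtracts the cohort median, which only
    represents the inactive baseline if active samples are a minority; the
    fixture therefore designates the last ~1/6 of samples (at least one) —
    a few patient samples against a background cohort.
    """
    n = params.n_samples
    k = max(1, n // 6)
    return [f"S{i:03d}" for i in range(n - k, n)]


def simulate_regulator_expression(
    network: RegulonNetwork,
    active: Iterable[str],
    params: SimParams,
) -> pd.DataFrame:
    """Expression matrix with planted regulator activity.

    Genes are the union of regulators and targets; samples are
    S000..S{n-1}. Baseline is iid Gaussian noise (sd = noise_sd). In the
    designated active samples (``active_sample_ids``), each active
    regulator's own expression rises by ``effect_size`` and its targets
    shift by sign x effect_size. With ``effect_size = 0`` the matrix is
    pure noise.
    """
    active = set(active)
    regs = set(network.regulators)
    unknown = active - regs
    if unknown:
        raise ValueError(f"active regulators not in network: {sorted(unknown)}")
    genes = sorted(regs | set(network.edges["target"]))
    samples = [f"S{i:03d}" for i in range(params.n_samples)]
    rng = params.rng(stream=4)
    x = rng.normal(0.0, params.noise_sd, size=(len(genes), len(samples)))
    df = pd.DataFrame(x, index=genes, columns=samples)
    hot = active_sample_ids(params)
    for reg in sorted(active):
        df.loc[reg, hot] += params.effect_size
        for _, t, sign in network.targets_of(reg).itertuples(index=False):
            df.loc[t, hot] += sign * params.effect_size
    return df


def simulate_rppa_cohort(
    proteins: Sequence[str],
    n_samples: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """RPPA-like protein-abundance cohort matrix (iid standard normal)."""
    rng = np.random.default_rng((int(seed), 5))
    cols = [f"C{i:03d}" for i in range(n_samples)]
    return pd.DataFrame(
        rng.normal(size=(len(proteins), n_samples)), index=list(proteins), columns=cols
    )


# ---------------------------------------------------------------------------
# spatial fixture
# ---------------------------------------------------------------------------

def simulate_spatial_tissue(params: SimParams) -> tuple[pd.DataFrame, ECMMask]:
    """Tumor nest with a collagen rim and a planted intensity gradient.

    A circular nest of radius ``nest_radius_um`` is surrounded by an
    annular ECM rim of width ``rim_width_um`` rendered into a binary mask
    at ``pixel_size_um``. Cells are uniform over the nest; the marker
    intensity of each cell is baseline - gradient_slope x (distance to the
    rim) + Gaussian noise, clipped at 0. Coordinates are in um with the
    image origin at the top-left.
    """
    rng = params.rng(stream=6)
    R = params.nest_radius_um
    rim = params.rim_width_um
    ps = params.pixel_size_um
    margin = 5.0
    size_um = 2 * (R + rim + margin)
    npix = int(np.ceil(size_um / ps))
    cx = cy = size_um / 2.0

    jj, ii = np.meshgrid(np.arange(npix), np.arange(npix))
    px = (jj + 0.5) * ps
    py = (ii + 0.5) * ps
    rad = np.hypot(px - cx, py - cy)
    mask = ECMMask(data=(rad >= R) & (rad < R + rim), pixel_size=ps)

    u = rng.random(params.n_cells)
    theta = rng.random(params.n_cells) * 2 * np.pi
    r = (R - 1.0) * np.sqrt(u)
    x = cx + r * np.cos(theta)
    y = cy + r * np.sin(theta)
    dist = R - r  # analytic distance to the rim's inner boundary
    intensity = (
        params.baseline_intensity
        - params.gradient_slope * dist
        + rng.normal(0.0, params.intensity_noise_sd, size=params.n_cells)
    )
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(params.n_cells)],
            X_COL: x,
            Y_COL: y,
            "marker": np.clip(intensity, 0.0, None),
            "roi": "ROI1",
        }
    )
    return cells, mask


# ---------------------------------------------------------------------------
# additive phylogenetic distances
# ---------------------------------------------------------------------------

def simulate_additive_distances(
    n_taxa: int, seed: int = 0
) -> tuple[pd.DataFrame, set[frozenset[str]]]:
    """Random tree-realizable (additive) distance matrix and its splits.

    A random unrooted binary topology is grown by attaching each new leaf
    to a uniformly chosen edge, with branch lengths uniform on [0.1, 1.0];
    leaf path lengths give the distance matrix. Returns the matrix and the
    generating tree's nontrivial bipartitions, for topology-recovery checks.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng((int(seed), 7))
    labels = [f"X{i}" for i in range(n_taxa)]
    n = n_taxa
    edges: dict[frozenset[int], float] = {
        frozenset((0, n)): rng.uniform(0.1, 1.0),
        frozenset((1, n)): rng.uniform(0.1, 1.0),
        frozenset((2, n)): rng.uniform(0.1, 1.0),
    }
    next_internal = n + 1
    for leaf in range(3, n):
        e = list(edges)[rng.integers(len(edges))]
        u, v = tuple(e)
        length = edges.pop(e)
        w = next_internal
        next_internal += 1
        split = rng.uniform(0.2, 0.8)
        edges[frozenset((u, w))] = length * split
        edges[frozenset((w, v))] = length * (1 - split)
        edges[frozenset((leaf, w))] = rng.uniform(0.1, 1.0)

    adj: dict[int, list[tuple[int, float]]] = {}
    for e, ln in edges.items():
        u, v = tuple(e)
        adj.setdefault(u, []).append((v, ln))
        adj.setdefault(v, []).append((u, ln))
    d = np.zeros((n, n))
    for leaf in range(n):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            a = stack.pop()
            for b, ln in adj[a]:
                if b not in dist:
                    dist[b] = dist[a] + ln
                    stack.append(b)
        for other in range(n):
            d[leaf, other] = dist[other]
    dm = pd.DataFrame(d, index=labels, columns=labels)

    splits = set()
    all_labels = frozenset(labels)
    for e in edges:
        u, v = tuple(e)
        seen = {u, v}
        stack = [u]
        side = set()
        while stack:
            a = stack.pop()
            if a < n:
                side.add(labels[a])
            for b, _ in adj[a]:
                if b not in seen:
                    seen.add(b)
                    stack.append(b)
        if 2 <= len(side) <= n - 2:
            other = all_labels - frozenset(side)
            splits.add(frozenset(min(sorted(side), sorted(other, key=str))))
    return dm, splits
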