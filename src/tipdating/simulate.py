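"""Synthetic-data generators.

Forward simulators producing inputs with the statistical structure the
inference stages assume: birth-death trees with fossil-sampled tips and
incomplete extant sampling, Mk-evolved discrete characters (ordered and
unordered, gamma rate heterogeneity, variable-only filtering), GTR+G(+I)
partitioned alignments, uniform stratigraphic age windows around true
fossil ages, six-area dispersal histories, and families of cusp-bearing
tooth meshes with class-level shape deformation.  Every generator takes
an explicit seed or Generator and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .characters import AREAS, MorphMatrix, MolecularSupermatrix, \
    TaxonRecord
from .models import SiteModel, build_rate_matrix, discrete_gamma_rates, \
    transition_probs
from .treemodel import Node, TimeTree


class SimulationError(RuntimeError):
    pass


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Scenario settings for a full synthetic dataset."""

    seed: int = 0
    # FBD process
    speciation: float = 0.15          # per lineage per Ma
    extinction: float = 0.05
    fossilization: float = 0.03       # psi
    rho: float = 1.0
    origin_age: float = 40.0
    min_tips: int = 3
    max_tips: int | None = None
    # characters
    n_morph: int = 100
    morph_states: int = 2
    frac_ordered: float = 0.0
    morph_gamma_shape: float | None = 1.0
    variable_only: bool = True
    # molecular
    n_sites: int = 2000
    n_subsets: int = 1
    dna_gamma_shape: float = 0.5
    p_invariant: float = 0.0
    # clock
    clock_rate: float = 0.01          # substitutions/site/Ma
    igr_variance: float = 0.0         # 0 = strict clock
    # biogeography
    dispersal_rate: float = 0.02      # per Ma, symmetric over 6 areas
    # fossil metadata
    window_width: float = 1.5         # Ma (Songhor-like bracket)


# ---------------------------------------------------------------------------
# FBD tree simulation


def simulate_fbd_tree(cfg: SimulationConfig, seed=None, min_tips: int = 3,
                      max_tips: int | None = None, max_tries: int = 200):
    """Forward birth-death simulation with fossil-sampled tips.

    Lineages speciate at rate ``speciation``, go extinct at
    ``extinction``, and are fossil-sampled at ``fossilization``; a
    fossil sample terminates its lineage so every fossil is a terminal
    tip (the fossil-tip sampling configuration).  Extant survivors are
    sampled with probability ``rho``.  Returns ``(TimeTree, truth)``
    where truth records the generating parameters and tip counts.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    lam, mu, psi = cfg.speciation, cfg.extinction, cfg.fossilization
    total = lam + mu + psi

    for attempt in range(max_tries):
        root = Node(None, cfg.origin_age)
        alive = [(root, cfg.origin_age)]
        fossils, extant = [], []
        n_events = 0
        overflow = False
        while alive:
            node, t = alive.pop()
            if total == 0:
                node.age = 0.0
                extant.append(node)
                continue
            wait = rng.exponential(1.0 / total)
            t_new = t - wait
            if t_new <= 0:
                node.age = 0.0
                extant.append(node)
                continue
            u = rng.random()
            node.age = t_new
            n_events += 1
            if n_events > 20000:
                overflow = True
                break
            if u < lam / total:
                for _ in range(2):
                    child = Node(None, t_new)
                    node.add_child(child)
                    alive.append((child, t_new))
            elif u < (lam + mu) / total:
                pass  # extinction: leaf, unsampled
            else:
                fossils.append(node)  # fossil-sampled, lineage terminates
        if overflow:
            continue

        sampled = set()
        for tip in extant:
            if rng.random() < cfg.rho:
                sampled.add(tip)
        sampled.update(fossils)
        if len(sampled) < min_tips:
            continue

        pruned = _prune_to_sampled(root, sampled)
        if pruned is None:
            continue
        n_leaves = len(_leaves(pruned))
        if n_leaves < min_tips or (max_tips is not None
                                   and n_leaves > max_tips):
            continue
        k_f = k_e = 0
        for leaf in _leaves(pruned):
            if leaf in fossils or leaf.age > 0:
                leaf.name = f"F{k_f}"
                k_f += 1
            else:
                leaf.name = f"X{k_e}"
                k_e += 1
        tree = TimeTree(pruned)
        tree.validate()
        truth = {"speciation": lam, "extinction": mu, "fossilization": psi,
                 "rho": cfg.rho, "origin_age": cfg.origin_age,
                 "n_extant": k_e, "n_fossil": k_f,
                 "n_extant_total": len(extant)}
        return tree, truth
    raise SimulationError(
        f"no surviving tree with >= {min_tips} sampled tips in "
        f"{max_tries} attempts")


def _leaves(node):
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.children:
            stack.extend(n.children)
        else:
            out.append(n)
    return out


def _prune_to_sampled(root, sampled):
    """Drop unsampled leaves and suppress unary nodes."""

    def prune(node):
        if not node.children:
            return node if node in sampled else None
        kept = [c for c in (prune(ch) for ch in node.children)
                if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        node.children = []
        for c in kept:
            node.add_child(c)
        return node

    new_root = prune(root)
    if new_root is not None:
        new_root.parent = None
    return new_root


# ---------------------------------------------------------------------------
# Character and sequence evolution


def _evolve_states(tree: TimeTree, Q: np.ndarray, site_rates: np.ndarray,
                   clock_rate: float, rng, root_states=None):
    """Evolve one CTMC per site down the tree; returns dict
    node -> state array."""
    k = Q.shape[0]
    pi = np.full(k, 1.0 / k) if Q[0].sum() == -Q[0, 0] else None
    # stationary frequencies from the null space (general case)
    w, v = np.linalg.eig(Q.T)
    pi = np.real(v[:, np.argmin(np.abs(w))])
    pi = np.abs(pi) / np.abs(pi).sum()
    n_sites = len(site_rates)
    states = {}
    if root_states is None:
        root_states = rng.choice(k, size=n_sites, p=pi)
    states[tree.root] = root_states
    unique_rates = np.unique(site_rates)
    for node in tree.preorder():
        if node.parent is None:
            continue
        bl = (node.parent.age - node.age) * node.rate * clock_rate
        parent_states = states[node.parent]
        out = np.empty(n_sites, dtype=int)
        for r in unique_rates:
            mask = site_rates == r
            P = transition_probs(Q, bl * r)
            cum = np.cumsum(P, axis=1)
            u = rng.random(int(mask.sum()))
            ps = parent_states[mask]
            out[mask] = (u[:, None] > cum[ps]).sum(axis=1)
        states[node] = out
    return states


def simulate_characters(tree: TimeTree, n_chars: int, k: int = 2,
                        ordered: bool = False,
                        gamma_shape: float | None = None,
                        clock_rate: float = 1.0,
                        variable_only: bool = True,
                        seed=0) -> MorphMatrix:
    """Mk-evolved discrete characters; constant characters are redrawn
    when ``variable_only`` (matching variable coding's data-generating
    assumption)."""
    rng = _rng(seed)
    Q = build_rate_matrix(SiteModel(family="mk", k=k, ordered=ordered))
    names = tree.tip_names()
    cols = []
    tries = 0
    while len(cols) < n_chars:
        batch = max(n_chars - len(cols), 8)
        rates = (rng.gamma(gamma_shape, 1.0 / gamma_shape, size=batch)
                 if gamma_shape else np.ones(batch))
        states = _evolve_states(tree, Q, rates, clock_rate, rng)
        tip_states = np.stack([states[t] for t in tree.tips])
        for j in range(batch):
            col = tip_states[:, j]
            if variable_only and len(np.unique(col)) < 2:
                continue
            cols.append(col)
            if len(cols) == n_chars:
                break
        tries += 1
        if tries > 200:
            raise SimulationError("cannot generate enough variable "
                                  "characters; tree too short?")
    cells = [[frozenset([int(cols[j][i])]) for j in range(n_chars)]
             for i in range(len(names))]
    return MorphMatrix(taxa=list(names), cells=cells,
                       n_states=np.full(n_chars, k),
                       ordered=np.full(n_chars, ordered))


_DNA_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def simulate_dna(tree: TimeTree, cfg: SimulationConfig, seed=0,
                 exchangeabilities=None, base_freqs=None
                 ) -> tuple[MolecularSupermatrix, dict]:
    """GTR+G(+I) sequences for ``cfg.n_subsets`` equal-length subsets."""
    rng = _rng(seed)
    names = tree.tip_names()
    per = cfg.n_sites // cfg.n_subsets
    blocks, segment_map, scheme, models, truth = [], [], {}, {}, {}
    pos = 0
    for s in range(cfg.n_subsets):
        ex = (np.asarray(exchangeabilities, dtype=float)
              if exchangeabilities is not None
              else rng.uniform(0.5, 3.0, size=6))
        fr = (np.asarray(base_freqs, dtype=float)
              if base_freqs is not None else rng.dirichlet(np.full(4, 20.0)))
        model = SiteModel(family="gtr", exchangeabilities=ex, base_freqs=fr)
        Q = build_rate_matrix(model)
        n = per if s < cfg.n_subsets - 1 else cfg.n_sites - pos
        rates = discrete_gamma_rates(cfg.dna_gamma_shape, 4)[
            rng.integers(4, size=n)]
        if cfg.p_invariant > 0:
            rates[rng.random(n) < cfg.p_invariant] = 0.0
        states = _evolve_states(tree, Q, rates, cfg.clock_rate, rng)
        blocks.append(np.stack([states[t] for t in tree.tips]))
        name = f"seg{s}"
        segment_map.append((name, pos, pos + n))
        scheme[name] = s
        models[s] = "GTR+I+G" if cfg.p_invariant > 0 else "GTR+G"
        truth[s] = {"exchangeabilities": ex, "base_freqs": fr,
                    "gamma_shape": cfg.dna_gamma_shape,
                    "p_invariant": cfg.p_invariant}
        pos += n
    sites = np.concatenate(blocks, axis=1).astype(np.uint8)
    return MolecularSupermatrix(list(names), sites, segment_map, scheme,
                                models), truth


# ---------------------------------------------------------------------------
# Metadata, biogeography, meshes


def assign_age_windows(tree: TimeTree, window_width: float = 1.5,
                       seed=0, areas: dict | None = None
                       ) -> list[TaxonRecord]:
    """Uniform stratigraphic windows containing each fossil's true age.

    The window has fixed width and a uniformly random offset, so across
    replicates the true age is uniformly positioned inside it (clipped
    at 0 for very young fossils); extant tips get [0, 0]."""
    rng = _rng(seed)
    records = []
    for tip in tree.tips:
        area = (areas or {}).get(tip.name)
        if tip.age == 0:
            records.append(TaxonRecord(tip.name, True, (0.0, 0.0), area))
        else:
            lo = tip.age - rng.uniform(0, window_width)
            lo = max(lo, 0.0)
            records.append(TaxonRecord(tip.name, False,
                                       (lo, lo + window_width), area))
    return records


def simulate_biogeography(tree: TimeTree, dispersal_rate: float = 0.02,
                          seed=0, rate_matrix: np.ndarray | None = None):
    """Six-area dispersal history as an unordered 6-state CTMC.

    Returns (tip_areas, true node areas by clade) so reconstruction
    accuracy can be scored against truth."""
    rng = _rng(seed)
    if rate_matrix is None:
        # normalized Mk scaled to `dispersal_rate` expected events/Ma
        Q = build_rate_matrix(SiteModel(family="mk", k=6)) * dispersal_rate
    else:
        Q = np.asarray(rate_matrix, dtype=float)
        if Q.shape != (6, 6):
            raise SimulationError("need a 6-state rate matrix")
    states = _evolve_states(tree, Q, np.ones(1), 1.0, rng)
    tip_areas = {t.name: AREAS[int(states[t][0])] for t in tree.tips}
    node_truth = {}
    for node in tree.postorder():
        if not node.is_leaf:
            clade = tree.clade_names(node)
            node_truth[clade] = AREAS[int(states[node][0])]
    return tip_areas, node_truth


# -- meshes


def _base_tooth_grid(n_grid: int = 24):
    """Parametric cusp-bearing crown: a dome with four cusps on a grid."""
    u = np.linspace(-1, 1, n_grid)
    X, Y = np.meshgrid(u, u)
    # asymmetric crown (distinct cusp heights/positions and a mesial
    # tilt) so rigid alignment has no spurious near-symmetries
    Z = 0.4 * (1 - 0.5 * (X ** 2 + Y ** 2)) + 0.12 * X + 0.06 * Y
    for cx, cy, h, w in [(-0.5, -0.45, 0.55, 0.22),
                         (0.5, -0.35, 0.32, 0.12),
                         (-0.35, 0.5, 0.20, 0.16),
                         (0.45, 0.45, 0.10, 0.09)]:
        Z += h * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / w)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = []
    for i in range(n_grid - 1):
        for j in range(n_grid - 1):
            a = i * n_grid + j
            faces.append([a, a + 1, a + n_grid])
            faces.append([a + 1, a + n_grid + 1, a + n_grid])
    return verts, np.asarray(faces)


def _smooth_field(verts, rng, magnitude):
    """Low-frequency smooth deformation field over the surface."""
    out = np.zeros_like(verts)
    for axis in range(3):
        w = rng.normal(0, 1, size=6)
        x, y, z = verts.T
        out[:, axis] = (w[0] * np.sin(1.5 * x) + w[1] * np.cos(1.5 * y)
                        + w[2] * x * y + w[3] * np.sin(2.0 * z)
                        + w[4] * x ** 2 + w[5] * y ** 2)
    rms = math.sqrt(np.mean(out ** 2)) or 1.0
    return magnitude * out / rms


def random_rotation(rng) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Qm, R = np.linalg.qr(A)
    Qm *= np.sign(np.diag(R))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] *= -1
    return Qm


def generate_tooth_meshes(n_classes: int = 2, n_per_class: int = 10,
                          deformation: float = 0.15, noise_sd: float = 0.01,
                          seed=0, mirror_fraction: float = 0.0,
                          n_grid: int = 24):
    """Mesh families with known class-level shape differences.

    Each class applies its own smooth deformation field to a common
    cusp-bearing base crown; each specimen adds per-vertex Gaussian
    jitter and a random rigid motion (optionally a mirror image).
    Returns (meshes, labels)."""
    import trimesh
    if deformation < 0 or noise_sd < 0:
        raise SimulationError("deformation and noise must be >= 0")
    rng = _rng(seed)
    base_verts, faces = _base_tooth_grid(n_grid)
    meshes, labels = [], []
    class_fields = [_smooth_field(base_verts, rng, deformation)
                    for _ in range(n_classes)]
    for c in range(n_classes):
        for _ in range(n_per_class):
            v = base_verts + class_fields[c]
            v = v + rng.normal(0, noise_sd, size=v.shape)
            R = random_rotation(rng)
            if mirror_fraction and rng.random() < mirror_fraction:
                R = R @ np.diag([1.0, 1.0, -1.0])
            v = v @ R.T + rng.normal(0, 0.5, size=3)
            meshes.append(trimesh.Trimesh(vertices=v, faces=faces,
                                          process=False))
            labels.append(c)
    return meshes, np.asarray(labels)


# ---------------------------------------------------------------------------
# Whole-scenario convenience


def simulate_dataset(cfg: SimulationConfig):
    """Simulate tree + characters + sequences + metadata in one call.

    Returns (CombinedDataset, TimeTree, truth) with independent seed
    streams per component, all derived from ``cfg.seed``."""
    from .characters import concatenate
    base = np.random.SeedSequence(cfg.seed).spawn(6)
    tree, truth = simulate_fbd_tree(cfg, seed=np.random.default_rng(base[0]),
                                    min_tips=cfg.min_tips,
                                    max_tips=cfg.max_tips)
    if cfg.igr_variance > 0:
        rng = np.random.default_rng(base[5])
        for node in tree.postorder():
            if node.parent is not None:
                d = node.parent.age - node.age
                node.rate = float(rng.gamma(d / cfg.igr_variance,
                                            cfg.igr_variance / d))
    n_ordered = int(round(cfg.frac_ordered * cfg.n_morph))
    char_rng = np.random.default_rng(base[1])
    morph = simulate_characters(
        tree, cfg.n_morph - n_ordered, k=cfg.morph_states,
        gamma_shape=cfg.morph_gamma_shape, clock_rate=cfg.clock_rate,
        variable_only=cfg.variable_only, seed=char_rng)
    if n_ordered:
        ordered_part = simulate_characters(
            tree, n_ordered, k=cfg.morph_states, ordered=True,
            gamma_shape=cfg.morph_gamma_shape, clock_rate=cfg.clock_rate,
            variable_only=cfg.variable_only, seed=char_rng)
        morph = MorphMatrix(
            taxa=morph.taxa,
            cells=[ro + rn for ro, rn in zip(ordered_part.cells,
                                             morph.cells)],
            n_states=np.concatenate([ordered_part.n_states,
                                     morph.n_states]),
            ordered=np.concatenate([ordered_part.ordered, morph.ordered]))
    mol = None
    if cfg.n_sites > 0:
        mol, dna_truth = simulate_dna(tree, cfg,
                                      seed=np.random.default_rng(base[2]))
        truth["dna"] = dna_truth
    areas, node_areas = simulate_biogeography(
        tree, cfg.dispersal_rate, seed=np.random.default_rng(base[3]))
    truth["node_areas"] = node_areas
    records = assign_age_windows(tree, cfg.window_width,
                                 seed=np.random.default_rng(base[4]),
                                 areas=areas)
    truth["tree"] = tree.to_newick()
    truth["root_age"] = tree.root.age
    truth["clock_rate"] = cfg.clock_rate
    data = concatenate(morph, mol, records)
    return data, tree, truth
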