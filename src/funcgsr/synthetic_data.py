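"""Synthetic cohorts with the ordering structure the GSR statistic consumes.

The generator emulates the case/control microarray design the pipeline is
built for: three diseases (endometriosis ES on endometrium; clear cell CCC and
endometrioid EC carcinomas on ovary), each with tissue-matched controls,
profiled on "platforms" that cover overlapping but unequal gene subsets.

Model.  Each gene ``g`` receives a baseline level ``mu_g`` drawn once from a
continuous distribution, which fixes a canonical expression ordering (ties
have probability zero).  Every sample's value is ``mu_g + Normal(0, noise_sd)``.
Deregulation of a gene set in a case sample is modelled as an ordering
scramble: a random ``ceil(f * |set|)``-subset of the set's values is permuted
among themselves within that sample.  Because the GSR index is purely
ordering-based, a mean shift that preserves order would be invisible to it;
the scramble fraction ``f`` is therefore the effect-size dial, and the
expected downstream GSR of a scrambled set decreases monotonically in ``f``.

Platform coverage is emulated per disease: a random ``1 - coverage`` fraction
of genes is dropped from that disease's datasets, forcing the downstream
common-gene integration step to do real work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionDataset, GeneSetCollection, GoDag


@dataclass
class DiseaseArm:
    name: str
    n_case: int
    n_control: int
    tissue: str


@dataclass
class SimulationDesign:
    """Full description of a synthetic multi-disease cohort.

    ``deregulation_plan`` maps each disease to a list of ``(set_name, f)``
    pairs: in every case sample of that disease, a ``ceil(f*|set|)``-subset of
    the named set's values is permuted.  ``platform_plan`` maps each disease to
    the fraction of the gene universe its platform covers.
    """

    n_genes: int
    n_sets: int
    set_size_range: tuple[int, int]
    diseases: list[DiseaseArm]
    deregulation_plan: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    platform_plan: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self, collection: GeneSetCollection | None = None) -> None:
        lo, hi = self.set_size_range
        if not (2 <= lo <= hi):
            raise ValueError(f"invalid set size range ({lo}, {hi})")
        if hi > self.n_genes:
            raise ValueError(f"max set size {hi} exceeds gene universe {self.n_genes}")
        for disease, plan in self.deregulation_plan.items():
            for set_name, f in plan:
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"scramble fraction {f} for {set_name!r} not in [0,1]")
                if collection is not None and set_name not in collection.sets:
                    raise ValueError(f"deregulation plan names unknown set {set_name!r}")
        for disease, cov in self.platform_plan.items():
            if not 0.0 < cov <= 1.0:
                raise ValueError(f"coverage {cov} for {disease!r} not in (0,1]")


def gen_gene_sets(
    n_genes: int,
    n_sets: int,
    size_range: tuple[int, int],
    seed: int,
    prefix: str = "GO_SET",
) -> GeneSetCollection:
    """Draw ``n_sets`` gene sets uniformly without replacement from a universe
    of ``n_genes`` symbols (``G0000``...).  Reproducible under ``seed``."""
    lo, hi = size_range
    if hi > n_genes:
        raise ValueError(f"set sizes up to {hi} infeasible with {n_genes} genes")
    if lo < 2:
        raise ValueError("minimum set size is 2 (orderings undefined below 2)")
    rng = np.random.default_rng(seed)
    universe = np.array([f"G{i:05d}" for i in range(n_genes)])
    sets = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        name = f"{prefix}_{k:04d}"
        sets[name] = {"description": f"synthetic set {k}", "genes": sorted(members)}
    return GeneSetCollection(sets=sets)


def gen_cohort(
    design: SimulationDesign, collection: GeneSetCollection
) -> dict[str, tuple[ExpressionDataset, ExpressionDataset]]:
    """Generate per-disease (case, control) expression datasets.

    Baselines are shared across all arms so tissue-matched controls carry the
    same canonical ordering; scrambling is applied only to case samples, only
    for the sets in that disease's plan.
    """
    design.validate(collection)
    rng = np.random.default_rng(design.seed)
    universe = [f"G{i:05d}" for i in range(design.n_genes)]
    gene_index = {g: i for i, g in enumerate(universe)}
    # uniform baselines: continuous, so canonical ordering is strict
    mu = rng.uniform(0.0, 10.0, size=design.n_genes)

    out: dict[str, tuple[ExpressionDataset, ExpressionDataset]] = {}
    for arm in design.diseases:
        plan = design.deregulation_plan.get(arm.name, [])
        set_members = [
            (np.array([gene_index[g] for g in collection.genes_of(s)]), f)
            for s, f in plan
        ]
        coverage = design.platform_plan.get(arm.name, 1.0)
        n_keep = max(1, int(round(coverage * design.n_genes)))
        keep = np.sort(rng.choice(design.n_genes, size=n_keep, replace=False))

        def make_samples(n: int, scramble: bool) -> np.ndarray:
            vals = mu[:, None] + rng.normal(0.0, design.noise_sd, size=(design.n_genes, n))
            if scramble:
                for j in range(n):
                    for members, f in set_members:
                        k = math.ceil(f * len(members))
                        if k < 2:
                            continue
                        chosen = rng.choice(members, size=k, replace=False)
                        vals[chosen, j] = vals[rng.permutation(chosen), j]
            return vals

        case_vals = make_samples(arm.n_case, scramble=True)
        ctrl_vals = make_samples(arm.n_control, scramble=False)

        def build(vals: np.ndarray, group: str, n: int) -> ExpressionDataset:
            ids = [f"{arm.name}_{group}_{i:03d}" for i in range(n)]
            return ExpressionDataset(
                platform_id=f"platform_{arm.name}",
                gene_ids=[universe[i] for i in keep],
                sample_ids=ids,
                values=vals[keep, :],
                sample_labels={
                    s: {"group": group, "disease": arm.name, "tissue": arm.tissue}
                    for s in ids
                },
            )

        out[arm.name] = (
            build(case_vals, "case", arm.n_case),
            build(ctrl_vals, "control", arm.n_control),
        )
    return out


def gen_godag(terms: list[str], branching: int, seed: int) -> GoDag:
    """Random rooted DAG: term i>0 gets 1..branching parents among terms 0..i-1.

    Acyclic by construction (edges always point to earlier terms)."""
    if not terms:
        raise ValueError("empty term list")
    if branching < 1:
        raise ValueError("branching must be >= 1")
    rng = np.random.default_rng(seed)
    edges: list[tuple[str, str]] = []
    for i, term in enumerate(terms):
        if i == 0:
            continue
        n_par = int(rng.integers(1, min(branching, i) + 1))
        parents = rng.choice(i, size=n_par, replace=False)
        for p in sorted(parents):
            edges.append((term, terms[p]))
    return GoDag(terms={t: t for t in terms}, edges=edges)


# ---------------------------------------------------------------------------
# Default study design
# ---------------------------------------------------------------------------

#: number of synthetic gene sets in each deregulation tier
N_ES_ONLY = 8
N_SHARED_CANCER = 10
N_TRANSFORMATION = 6


def default_eaoc_design(
    seed: int,
    n_genes: int = 2000,
    n_sets: int = 200,
    n_case: int = 40,
    n_control: int = 100,
    noise_sd: float = 1.0,
) -> SimulationDesign:
    """Desk-scale three-disease design with an overlapping deregulation
    architecture.

    Three tiers of deregulated sets are planted among ``n_sets`` total:

    * ``ES``-only sets, scrambled strongly (f=0.7) in ES cases alone;
    * shared cancer sets, scrambled at f=0.5 in both CCC and EC;
    * "transformation" sets, scrambled in all three diseases with graded
      strength (mild f=0.3 in ES rising to f=0.9 in CCC/EC), so that their
      case-group GSR drops and their deregulation rank improves from ES to
      both cancers — the signature the progression filter extracts.

    The grading is deliberately wide.  At n=40/100 the Mann-Whitney p of a
    fully separated set saturates near its asymptotic floor, and ranks among
    saturated sets are noise; the tiers are therefore spaced so that the
    transformation sets saturate in the cancers but sit clearly below the
    ES-only tier in ES, which keeps their rank movement (ES rank above both
    cancer ranks) a property of the construction rather than of tie-breaking.
    Set sizes are kept in a narrow band for the same reason.

    ES arms use endometrium tissue, CCC/EC use ovary; platform coverage
    differs per disease to exercise common-gene integration.
    """
    set_names = [f"GO_SET_{k:04d}" for k in range(n_sets)]
    es_only = set_names[:N_ES_ONLY]
    shared = set_names[N_ES_ONLY : N_ES_ONLY + N_SHARED_CANCER]
    transform = set_names[
        N_ES_ONLY + N_SHARED_CANCER : N_ES_ONLY + N_SHARED_CANCER + N_TRANSFORMATION
    ]
    plan = {
        "ES": [(s, 0.7) for s in es_only] + [(s, 0.3) for s in transform],
        "CCC": [(s, 0.5) for s in shared] + [(s, 0.9) for s in transform],
        "EC": [(s, 0.5) for s in shared] + [(s, 0.9) for s in transform],
    }
    return SimulationDesign(
        n_genes=n_genes,
        n_sets=n_sets,
        set_size_range=(8, 12),
        diseases=[
            DiseaseArm("ES", n_case, n_control, "endometrium"),
            DiseaseArm("CCC", n_case, n_control, "ovary"),
            DiseaseArm("EC", n_case, n_control, "ovary"),
        ],
        deregulation_plan=plan,
        platform_plan={"ES": 0.95, "CCC": 0.9, "EC": 0.92},
        noise_sd=noise_sd,
        seed=seed,
    )


def transformation_sets(design: SimulationDesign) -> list[str]:
    """Sets planted as progressively deregulated (present in every arm's plan
    with strictly larger f in the cancers than in ES)."""
    plans = {d: dict(p) for d, p in design.deregulation_plan.items()}
    if not {"ES", "CCC", "EC"} <= set(plans):
        return []
    out = []
    for s, f_es in plans["ES"].items():
        if s in plans["CCC"] and s in plans["EC"]:
            if plans["CCC"][s] > f_es and plans["EC"][s] > f_es:
                out.append(s)
    return sorted(out)
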