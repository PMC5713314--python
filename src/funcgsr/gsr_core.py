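"""Gene set regularity (GSR) scoring.

A gene set's *rank template* records, for every unordered pair of member genes,
which of the two is more highly expressed in the majority of control samples
(the differential rank conservation construction).  A sample's GSR index for
the set is then the fraction of template pairs whose ordering the sample
reproduces: 1 means the control-consensus ordering is fully conserved, 0 that
it is fully reversed.  Scoring every sample against every surviving gene set
yields the *functionome* — a samples x sets matrix of indices in [0, 1].

Tie conventions (deterministic by design):

* a tie in expression values within a sample counts as NOT satisfying
  ``expr_i > expr_j`` (strict inequality);
* an even split in the control majority vote sets the template bit to the
  lexicographically earlier gene being higher; such ties are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionDataset, GeneSetCollection

logger = logging.getLogger("funcgsr")

#: sets reduced below this many available genes are dropped during pruning
DEFAULT_MIN_SET_SIZE = 2

#: minimum common genes required when integrating datasets (study rule: 8000;
#: scale down for desk-size synthetic universes)
DEFAULT_MIN_COMMON_GENES = 8000


@dataclass
class RankTemplate:
    """Majority pairwise ordering of a gene set over control samples.

    ``pair_bits[k]`` corresponds to the k-th pair ``(i, j)`` with ``i < j`` in
    ``genes`` order (``numpy.triu_indices`` convention) and is True iff
    ``genes[i]`` exceeds ``genes[j]`` in the majority of controls.
    """

    set_name: str
    genes: list[str]
    pair_bits: np.ndarray

    def __post_init__(self) -> None:
        g = len(self.genes)
        expected = g * (g - 1) // 2
        if len(self.pair_bits) != expected:
            raise ValueError(
                f"{self.set_name}: {len(self.pair_bits)} pair bits for {g} genes "
                f"(expected {expected})"
            )


@dataclass
class FunctionomeMatrix:
    """Samples x gene sets matrix of GSR indices, labels carried through."""

    sample_ids: list[str]
    set_names: list[str]
    gsr: np.ndarray
    sample_labels: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        self.gsr = np.asarray(self.gsr, dtype=float)
        if self.gsr.shape != (len(self.sample_ids), len(self.set_names)):
            raise ValueError("GSR matrix shape does not match id lists")
        if self.gsr.size and (self.gsr.min() < 0 or self.gsr.max() > 1):
            raise ValueError("GSR entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gsr, index=self.sample_ids, columns=self.set_names)

    def groups(self) -> pd.Series:
        return pd.Series(
            [self.sample_labels[s]["group"] for s in self.sample_ids],
            index=self.sample_ids,
        )

    def rows_for(self, group: str | None = None, disease: str | None = None) -> np.ndarray:
        """Boolean row mask by group and/or disease label."""
        mask = np.ones(len(self.sample_ids), dtype=bool)
        for i, s in enumerate(self.sample_ids):
            lab = self.sample_labels[s]
            if group is not None and lab["group"] != group:
                mask[i] = False
            if disease is not None and lab["disease"] != disease:
                mask[i] = False
        return mask


# ---------------------------------------------------------------------------
# Dataset integration and gene-set pruning
# ---------------------------------------------------------------------------


def integrate_common_genes(
    datasets: list[ExpressionDataset],
    min_common_genes: int = DEFAULT_MIN_COMMON_GENES,
) -> ExpressionDataset:
    """Concatenate samples across datasets, restricted to the common genes.

    Mirrors the study's discard rule: an integration whose common-gene count
    falls below ``min_common_genes`` is rejected, naming the dataset whose
    inclusion caused the shortfall.
    """
    if not datasets:
        raise ValueError("no datasets to integrate")
    if len(datasets) == 1:
        return datasets[0]

    common = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        new_common = common & set(ds.gene_ids)
        if not new_common:
            raise ValueError(f"empty gene intersection when adding {ds.platform_id!r}")
        if len(new_common) < min_common_genes:
            raise ValueError(
                f"integrating dataset {ds.platform_id!r} leaves "
                f"{len(new_common)} common genes (< {min_common_genes})"
            )
        common = new_common

    genes = sorted(common)
    sample_ids: list[str] = []
    labels: dict[str, dict[str, str]] = {}
    blocks = []
    for ds in datasets:
        idx = [ds.gene_ids.index(g) for g in genes] if len(genes) < 5000 else None
        if idx is None:
            pos = {g: i for i, g in enumerate(ds.gene_ids)}
            idx = [pos[g] for g in genes]
        blocks.append(ds.values[np.asarray(idx), :])
        sample_ids.extend(ds.sample_ids)
        labels.update({s: dict(ds.sample_labels[s]) for s in ds.sample_ids})
    integrated = ExpressionDataset(
        platform_id="+".join(ds.platform_id for ds in datasets),
        gene_ids=genes,
        sample_ids=sample_ids,
        values=np.concatenate(blocks, axis=1),
        sample_labels=labels,
    )
    logger.info(
        "integrated %d datasets: %d common genes, %d samples",
        len(datasets),
        integrated.n_genes,
        integrated.n_samples,
    )
    return integrated


def prune_gene_sets(
    collection: GeneSetCollection,
    available_genes: set[str] | list[str],
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> GeneSetCollection:
    """Restrict every set to the available genes; drop sets that shrink below
    ``min_set_size`` members.  The platform-driven shrink from a full GO
    collection to the usable subset emerges here rather than from any list."""
    if min_set_size < 2:
        raise ValueError("min_set_size must be >= 2")
    avail = set(available_genes)
    kept, dropped = {}, []
    for name, entry in collection.sets.items():
        genes = [g for g in entry["genes"] if g in avail]
        if len(genes) >= min_set_size:
            kept[name] = {"description": entry["description"], "genes": genes}
        else:
            dropped.append(name)
    if dropped:
        logger.info("pruned %d/%d gene sets below %d available members",
                    len(dropped), len(collection.sets), min_set_size)
    if not kept:
        logger.warning("no gene sets survive pruning")
    return GeneSetCollection(sets=kept)


# ---------------------------------------------------------------------------
# Rank templates and matching scores
# ---------------------------------------------------------------------------


def build_rank_template(controls: ExpressionDataset, set_name: str, genes: list[str]) -> RankTemplate:
    """Per-pair majority vote over control samples.

    For each unordered pair ``(i, j)`` (i < j in ``genes`` order) the template
    bit is True iff ``genes[i] > genes[j]`` in strictly more than half of the
    controls; an exact even split falls back to lexicographic order.
    """
    pos = {g: i for i, g in enumerate(controls.gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValueError(f"set {set_name!r}: genes absent from platform: {missing[:5]}")
    if len(genes) < 2:
        raise ValueError(f"set {set_name!r}: need >= 2 genes for orderings")
    vals = controls.values[np.asarray([pos[g] for g in genes]), :]  # G x S
    n = vals.shape[1]
    if n < 1:
        raise ValueError("no control samples")
    iu, ju = np.triu_indices(len(genes), k=1)
    votes = (vals[iu, :] > vals[ju, :]).sum(axis=1)  # strict inequality
    bits = votes * 2 > n
    even = votes * 2 == n
    if even.any():
        # even split: lexicographically earlier gene wins the "higher" slot
        garr = np.asarray(genes)
        bits = np.where(even, garr[iu] < garr[ju], bits)
        logger.debug("set %s: %d even-split pairs tie-broken lexicographically",
                     set_name, int(even.sum()))
    return RankTemplate(set_name=set_name, genes=list(genes), pair_bits=bits)


def rank_matching_score(profile: dict[str, float] | pd.Series, template: RankTemplate) -> float:
    """Fraction of template pairs whose ordering the profile reproduces.

    Equals ``1 - kendall_distance / C(G, 2)`` against the template ordering
    when the template is a total order.  Ties in the profile count as not
    satisfying the strict inequality, i.e. they match only templates whose bit
    points the other way.
    """
    if isinstance(profile, pd.Series):
        profile = profile.to_dict()
    missing = [g for g in template.genes if g not in profile]
    if missing:
        raise ValueError(f"profile missing genes {missing[:5]} for set {template.set_name!r}")
    vals = np.asarray([profile[g] for g in template.genes], dtype=float)
    iu, ju = np.triu_indices(len(template.genes), k=1)
    observed = vals[iu] > vals[ju]
    return float(np.mean(observed == template.pair_bits))


def compute_functionome(
    cohort: ExpressionDataset,
    collection: GeneSetCollection,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    templates: dict[str, RankTemplate] | None = None,
) -> FunctionomeMatrix:
    """Score every sample (cases AND controls) against every surviving set.

    Templates are learned from the cohort's control samples only, then applied
    to all samples; pass ``templates`` to reuse previously learned ones (e.g.
    scoring merged cancer cases against shared ovarian-control templates).
    """
    groups = cohort.groups()
    control_ids = [s for s in cohort.sample_ids if groups[s] == "control"]
    if templates is None and not control_ids:
        raise ValueError("no control samples to learn rank templates from")

    pruned = prune_gene_sets(collection, cohort.gene_ids, min_set_size=min_set_size)
    pos = {g: i for i, g in enumerate(cohort.gene_ids)}
    ctrl_cols = np.asarray([cohort.sample_ids.index(s) for s in control_ids], dtype=int)

    set_names = []
    scores = np.empty((cohort.n_samples, len(pruned.sets)))
    made_templates: dict[str, RankTemplate] = {}
    for k, (name, entry) in enumerate(pruned.sets.items()):
        genes = entry["genes"]
        gidx = np.asarray([pos[g] for g in genes])
        vals = cohort.values[gidx, :]  # G x S
        iu, ju = np.triu_indices(len(genes), k=1)
        pair_gt = vals[iu, :] > vals[ju, :]  # P x S
        if templates is not None:
            tmpl = templates[name]
            if tmpl.genes != genes:
                # re-express template bits on this cohort's available genes
                tmpl = _restrict_template(tmpl, genes)
            bits = tmpl.pair_bits
        else:
            votes = pair_gt[:, ctrl_cols].sum(axis=1)
            n = len(ctrl_cols)
            bits = votes * 2 > n
            even = votes * 2 == n
            if even.any():
                garr = np.asarray(genes)
                bits = np.where(even, garr[iu] < garr[ju], bits)
            tmpl = RankTemplate(set_name=name, genes=list(genes), pair_bits=bits)
        made_templates[name] = tmpl
        scores[:, k] = (pair_gt == bits[:, None]).mean(axis=0)
        set_names.append(name)

    fm = FunctionomeMatrix(
        sample_ids=list(cohort.sample_ids),
        set_names=set_names,
        gsr=scores,
        sample_labels={s: dict(cohort.sample_labels[s]) for s in cohort.sample_ids},
    )
    fm.templates = made_templates  # stashed for reuse / serialization
    return fm


def _restrict_template(tmpl: RankTemplate, genes: list[str]) -> RankTemplate:
    """Project a template onto a subset of its genes (platform mismatch)."""
    keep = [g for g in genes if g in set(tmpl.genes)]
    if keep != genes:
        missing = [g for g in genes if g not in set(tmpl.genes)]
        raise ValueError(f"template {tmpl.set_name!r} lacks genes {missing[:5]}")
    old_pos = {g: i for i, g in enumerate(tmpl.genes)}
    iu_old, ju_old = np.triu_indices(len(tmpl.genes), k=1)
    bit_lookup = {}
    for a, b, bit in zip(iu_old, ju_old, tmpl.pair_bits):
        bit_lookup[(a, b)] = bool(bit)
    iu, ju = np.triu_indices(len(genes), k=1)
    bits = np.empty(len(iu), dtype=bool)
    for k, (i, j) in enumerate(zip(iu, ju)):
        a, b = old_pos[genes[i]], old_pos[genes[j]]
        if a < b:
            bits[k] = bit_lookup[(a, b)]
        else:
            bits[k] = not bit_lookup[(b, a)]
    return RankTemplate(set_name=tmpl.set_name, genes=list(genes), pair_bits=bits)
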