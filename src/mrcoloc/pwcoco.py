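"""Pairwise conditional colocalization over one region.

Strategy: colocalize the unconditional summary statistics first; if
PP.H4 clears the evidence threshold, stop. Otherwise select the
conditionally independent signals of each trait, build one conditional
dataset per signal (conditioning on the other signals so that each
dataset isolates one signal), and colocalize every combination of
{unconditional + conditional} datasets for the two traits, reporting the
maximum PP.H4 over all evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mrcoloc.cojo import CojoWorkspace, ConditionalDataset, conditional_stats, stepwise_select
from mrcoloc.coloc import ColocPosterior, ColocPriors, abf, coloc_posteriors


@dataclass
class PWCoCoConfig:
    priors: ColocPriors = field(default_factory=ColocPriors)
    prior_sd1: float = 0.15
    prior_sd2: float = 0.15
    pp4_threshold: float = 0.8  # evidence rule: best_pp4 >= threshold
    p_cutoff: float = 5e-8
    collinearity_r2: float = 0.9
    single_signal_condition: bool = False


@dataclass
class PWCoCoResult:
    region_id: str
    unconditional: ColocPosterior
    conditional: list[tuple[str, ColocPosterior]]
    best_pp4: float
    best_combination: str
    evidence: bool
    selected1: list[str]
    selected2: list[str]

    @property
    def all_posteriors(self) -> list[tuple[str, ColocPosterior]]:
        return [("unconditional/unconditional", self.unconditional)] + self.conditional

    @property
    def n_evaluations(self) -> int:
        return 1 + len(self.conditional)


def make_conditional_datasets(
    workspace: CojoWorkspace,
    selected: list[str] | None = None,
    p_cutoff: float = 5e-8,
    collinearity_r2: float = 0.9,
    single_signal_condition: bool = False,
) -> list[ConditionalDataset]:
    """Signal-isolating conditional datasets for one trait.

    With k >= 2 selected signals, dataset s conditions on the other k-1
    signals. With k == 1 the unconditional data already isolate the
    signal; ``single_signal_condition`` additionally conditions on that
    single SNP. k == 0 yields no datasets.
    """
    if selected is None:
        selected = stepwise_select(workspace, p_cutoff, collinearity_r2)
    k = len(selected)
    datasets: list[ConditionalDataset] = []
    if k >= 2:
        for s in selected:
            others = [t for t in selected if t != s]
            ds = conditional_stats(workspace, others, collinearity_r2)
            ds.isolated = s
            datasets.append(ds)
    elif k == 1 and single_signal_condition:
        ds = conditional_stats(workspace, selected, collinearity_r2)
        ds.isolated = None
        datasets.append(ds)
    return datasets


def _coloc_datasets(
    ds1: ConditionalDataset,
    ds2: ConditionalDataset,
    config: PWCoCoConfig,
    trait_type1: str,
    trait_type2: str,
) -> ColocPosterior | None:
    ids1, b1, se1 = ds1.arrays()
    ids2, b2, se2 = ds2.arrays()
    common = [s for s in ids1 if s in set(ids2)]
    if not common:
        return None
    i1 = {s: j for j, s in enumerate(ids1)}
    i2 = {s: j for j, s in enumerate(ids2)}
    sel1 = [i1[s] for s in common]
    sel2 = [i2[s] for s in common]
    a1 = abf(common, b1[sel1], se1[sel1], trait_type1, config.prior_sd1)
    a2 = abf(common, b2[sel2], se2[sel2], trait_type2, config.prior_sd2)
    label = f"{ds1.label}/{ds2.label}"
    return coloc_posteriors(a1, a2, config.priors, label=label)


def run_pwcoco(
    workspace1: CojoWorkspace,
    workspace2: CojoWorkspace,
    config: PWCoCoConfig | None = None,
    trait_type1: str = "quantitative",
    trait_type2: str = "binary",
    region_id: str = "",
) -> PWCoCoResult:
    """Run the full pairwise conditional colocalization search."""
    config = config or PWCoCoConfig()
    uncond1 = workspace1.to_conditional_dataset()
    uncond2 = workspace2.to_conditional_dataset()
    unconditional = _coloc_datasets(
        uncond1, uncond2, config, trait_type1, trait_type2
    )
    if unconditional is None:
        raise ValueError("no SNP shared between the two traits in this region")

    if unconditional.pp4 >= config.pp4_threshold:
        return PWCoCoResult(
            region_id=region_id,
            unconditional=unconditional,
            conditional=[],
            best_pp4=unconditional.pp4,
            best_combination="unconditional/unconditional",
            evidence=True,
            selected1=[],
            selected2=[],
        )

    selected1 = stepwise_select(workspace1, config.p_cutoff, config.collinearity_r2)
    selected2 = stepwise_select(workspace2, config.p_cutoff, config.collinearity_r2)
    conds1 = make_conditional_datasets(
        workspace1, selected1, config.p_cutoff, config.collinearity_r2,
        config.single_signal_condition,
    )
    conds2 = make_conditional_datasets(
        workspace2, selected2, config.p_cutoff, config.collinearity_r2,
        config.single_signal_condition,
    )

    evaluated: list[tuple[str, ColocPosterior]] = []
    for ds1 in [uncond1] + conds1:
        for ds2 in [uncond2] + conds2:
            if not ds1.conditioning and not ds2.conditioning:
                continue  # the unconditional pair is already done
            post = _coloc_datasets(ds1, ds2, config, trait_type1, trait_type2)
            if post is not None:
                evaluated.append((post.label, post))

    best_label, best = "unconditional/unconditional", unconditional
    for label, post in evaluated:
        if post.pp4 > best.pp4:
            best_label, best = label, post
    return PWCoCoResult(
        region_id=region_id,
        unconditional=unconditional,
        conditional=evaluated,
        best_pp4=best.pp4,
        best_combination=best_label,
        evidence=best.pp4 >= config.pp4_threshold,
        selected1=selected1,
        selected2=selected2,
    )
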