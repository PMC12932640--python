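"""Approximate conditional/joint association from summary statistics.

Reconstructs the multiple-regression normal equations from marginal
(beta, se, eaf, n) plus a reference LD panel:

    (X'X)_ij ~ r_ij * sqrt(D_i * D_j),   (X'y)_j = D_j * b_j

where D_j approximates the centered dosage sum of squares — by default
n_j times the reference-panel dosage variance (exact when the panel is
the GWAS cohort), optionally the HWE form 2 f_j (1 - f_j) n_j —

with the regional phenotypic sum of squares Syy estimated as the median
over SNPs of D_j (b_j^2 + (n_j - 2) se_j^2). Conditional statistics for a
SNP are obtained by refitting the joint model on the conditioning set
plus that SNP. Stepwise selection iterates conditional p-values to find
conditionally independent signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from mrcoloc.ld import GenotypePanel
from mrcoloc.sumstats import SumStatTable

logger = logging.getLogger(__name__)


class CollinearityError(ValueError):
    """The requested joint model is (near-)singular."""


class InconsistentSummaryDataError(ValueError):
    """Summary statistics imply a negative residual variance."""


@dataclass
class ConditionalRecord:
    snp_id: str
    beta: float
    se: float
    pvalue: float
    collinear: bool = False


@dataclass
class ConditionalDataset:
    """Conditional summary statistics given a conditioning SNP set."""

    trait_id: str
    conditioning: list[str]
    records: list[ConditionalRecord]
    isolated: str | None = None  # the selected signal this dataset isolates

    @property
    def label(self) -> str:
        if not self.conditioning:
            return "unconditional"
        return "cond(" + ",".join(self.conditioning) + ")"

    def arrays(self, drop_collinear: bool = True) -> tuple[list[str], np.ndarray, np.ndarray]:
        recs = [r for r in self.records if not (drop_collinear and r.collinear)]
        ids = [r.snp_id for r in recs]
        beta = np.array([r.beta for r in recs])
        se = np.array([r.se for r in recs])
        return ids, beta, se


class CojoWorkspace:
    """Summary statistics plus reference LD for one trait over one region.

    SNPs absent from the reference panel are dropped at construction with
    a warning; a |EAF - panel frequency| mismatch above ``freq_warn``
    is warn-only.
    """

    def __init__(
        self,
        table: SumStatTable,
        panel: GenotypePanel,
        freq_warn: float = 0.2,
        cond_threshold: float = 1e8,
        hwe_d: bool = False,
    ) -> None:
        ids = [s for s in table.snp_ids if s in panel]
        dropped = len(table) - len(ids)
        if dropped:
            logger.warning("dropped %d SNP(s) absent from the reference panel", dropped)
        if not ids:
            raise ValueError("no SNP shared between summary statistics and panel")
        self.trait_id = table.trait_id
        self.snp_ids = ids
        self._idx = {s: j for j, s in enumerate(ids)}
        recs = [table[s] for s in ids]
        self.b = np.array([r.beta for r in recs])
        self.se = np.array([r.se for r in recs])
        self.f = np.array([r.eaf for r in recs])
        self.n = np.array([r.n for r in recs])
        self.cond_threshold = cond_threshold

        for s, f in zip(ids, self.f):
            pf = panel.allele_freq(s)
            if abs(f - pf) > freq_warn and abs((1 - f) - pf) > freq_warn:
                logger.warning("allele frequency mismatch for %s: gwas=%.3f panel=%.3f",
                               s, f, pf)

        if hwe_d:
            # textbook HWE approximation of the centered sum of squares
            self.D = 2.0 * self.f * (1.0 - self.f) * self.n
        else:
            # realized dosage variance from the reference panel; exact when
            # the panel is the GWAS cohort, and an equally valid estimator
            # otherwise
            var_ref = np.array([panel.column(s).var() for s in ids])
            self.D = var_ref * self.n
        if np.any(self.D <= 0):
            raise ValueError("non-positive D_j; check EAF and N fields")
        syy_j = self.D * (self.b**2 + (self.n - 2.0) * self.se**2)
        self.Syy = float(np.median(syy_j))
        if self.Syy <= 0:
            raise ValueError("non-positive Syy estimate")
        self.n_eff = float(np.median(self.n))
        self._corr = panel.corr_matrix(ids)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def index(self, snp_id: str) -> int:
        try:
            return self._idx[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in workspace") from None

    def r(self, snp_a: str, snp_b: str) -> float:
        return float(self._corr[self.index(snp_a), self.index(snp_b)])

    def marginal_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.b / self.se))

    def to_conditional_dataset(self) -> ConditionalDataset:
        """The unconditional data wrapped in the conditional container."""
        p = self.marginal_p()
        return ConditionalDataset(
            trait_id=self.trait_id,
            conditioning=[],
            records=[
                ConditionalRecord(s, float(b), float(se), float(pv))
                for s, b, se, pv in zip(self.snp_ids, self.b, self.se, p)
            ],
        )


def joint_fit(
    workspace: CojoWorkspace, snp_set: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint (multi-SNP) effect estimates for ``snp_set``.

    Returns (betas, ses, pvalues) in the order of ``snp_set``.
    """
    if not snp_set:
        raise ValueError("snp_set must be non-empty")
    idx = np.array([workspace.index(s) for s in snp_set])
    d = workspace.D[idx]
    r = workspace._corr[np.ix_(idx, idx)]
    xtx = r * np.sqrt(np.outer(d, d))
    xty = d * workspace.b[idx]

    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > workspace.cond_threshold:
        raise CollinearityError(
            f"near-singular joint model for SNPs {list(snp_set)} (cond={cond:.3g})"
        )
    beta = np.linalg.solve(xtx, xty)
    dof = workspace.n_eff - len(snp_set) - 1.0
    if dof <= 0:
        raise ValueError("not enough effective samples for the joint fit")
    sigma2 = (workspace.Syy - float(beta @ xty)) / dof
    if sigma2 <= 0:
        raise InconsistentSummaryDataError(
            f"negative residual variance ({sigma2:.3g}) for SNPs {list(snp_set)}"
        )
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(xtx)))
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return beta, se, p


def conditional_stats(
    workspace: CojoWorkspace,
    conditioning: Sequence[str],
    collinearity_r2: float = 0.9,
) -> ConditionalDataset:
    """Per-SNP statistics conditional on ``conditioning``.

    Each remaining SNP is refit jointly with the conditioning set and its
    own coefficient reported. SNPs whose reference r-squared with any
    conditioning SNP exceeds ``collinearity_r2`` are flagged collinear
    and carried with conditional beta 0 and their marginal se.
    """
    cond = list(conditioning)
    if not cond:
        return workspace.to_conditional_dataset()
    cond_idx = [workspace.index(s) for s in cond]
    records: list[ConditionalRecord] = []
    for s in workspace.snp_ids:
        if s in cond:
            continue
        j = workspace.index(s)
        r2_max = float(np.max(workspace._corr[j, cond_idx] ** 2))
        if r2_max > collinearity_r2:
            records.append(
                ConditionalRecord(s, 0.0, float(workspace.se[j]), 1.0, collinear=True)
            )
            continue
        try:
            beta, se, p = joint_fit(workspace, cond + [s])
        except (CollinearityError, InconsistentSummaryDataError):
            records.append(
                ConditionalRecord(s, 0.0, float(workspace.se[j]), 1.0, collinear=True)
            )
            continue
        records.append(ConditionalRecord(s, float(beta[-1]), float(se[-1]), float(p[-1])))
    return ConditionalDataset(trait_id=workspace.trait_id, conditioning=cond, records=records)


def conditional_association(
    workspace: CojoWorkspace,
    target_snp: str,
    conditioning: Sequence[str],
    collinearity_r2: float = 0.9,
) -> tuple[float, float, float]:
    """(beta, se, p) of ``target_snp`` adjusted for ``conditioning``."""
    if target_snp in conditioning:
        raise ValueError("target SNP cannot be in the conditioning set")
    j = workspace.index(target_snp)
    if not conditioning:
        b, se = float(workspace.b[j]), float(workspace.se[j])
        return b, se, float(2.0 * stats.norm.sf(abs(b / se)))
    ds = conditional_stats(workspace, conditioning, collinearity_r2)
    for rec in ds.records:
        if rec.snp_id == target_snp:
            return rec.beta, rec.se, rec.pvalue
    raise KeyError(f"target SNP {target_snp!r} not in workspace")


def stepwise_select(
    workspace: CojoWorkspace,
    p_cutoff: float = 5e-8,
    collinearity_r2: float = 0.9,
) -> list[str]:
    """Stepwise selection of conditionally independent signals.

    Seeds with the minimum-p SNP; repeatedly admits the candidate with
    the smallest conditional p-value (subject to the collinearity cutoff),
    dropping any selected SNP whose joint p-value rises above the cutoff.
    Tie-breaks are deterministic: p, then |z| descending, then snp_id.
    """
    p_marg = workspace.marginal_p()
    z_abs = np.abs(workspace.b / workspace.se)

    def order_key(snp_id: str, p: float, z: float):
        return (p, -z, snp_id)

    candidates = sorted(
        workspace.snp_ids,
        key=lambda s: order_key(s, p_marg[workspace.index(s)], z_abs[workspace.index(s)]),
    )
    if not candidates or p_marg[workspace.index(candidates[0])] >= p_cutoff:
        return []
    selected = [candidates[0]]

    for _ in range(len(workspace)):  # hard bound against admit/drop cycles
        ds = conditional_stats(workspace, selected, collinearity_r2)
        best: tuple | None = None
        for rec in ds.records:
            if rec.collinear or rec.pvalue >= p_cutoff:
                continue
            z = abs(rec.beta / rec.se) if rec.se > 0 else 0.0
            key = order_key(rec.snp_id, rec.pvalue, z)
            if best is None or key < best[0]:
                best = (key, rec.snp_id)
        if best is None:
            break
        selected.append(best[1])
        # backward step: drop signals that lost joint significance
        _, _, pj = joint_fit(workspace, selected)
        keep = [s for s, p in zip(selected, pj) if p < p_cutoff]
        if len(keep) < len(selected):
            if best[1] not in keep:
                # the admission invalidated itself; undo and stop
                selected = [s for s in selected if s != best[1]]
                break
            selected = keep
    return sorted(selected, key=lambda s: workspace.index(s))


def conditional_table(dataset: ConditionalDataset, base: SumStatTable) -> SumStatTable:
    """Render a conditional dataset back into summary-statistic form,
    reusing the base table's per-SNP metadata."""
    out = SumStatTable(
        f"{base.trait_id}|{dataset.label}", trait_type=base.trait_type
    )
    from dataclasses import replace as _replace

    for rec in dataset.records:
        if rec.collinear:
            continue
        orig = base.get(rec.snp_id)
        if orig is None:
            continue
        out.add(_replace(orig, beta=rec.beta, se=rec.se,
                         pvalue=max(min(rec.pvalue, 1.0), np.nextafter(0, 1))))
    return out
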