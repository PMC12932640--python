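"""Reference genotype panel and pairwise LD (r, r-squared, D-prime).

LD is genotypic: r is the Pearson correlation of dosage columns.
D-prime is computed from haplotype frequencies estimated with the
standard two-locus EM algorithm on unphased genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class DegenerateLDError(ValueError):
    """A dosage column involved in an LD computation is constant."""


class EMConvergenceError(RuntimeError):
    """Two-locus EM failed to converge; carries the last estimate."""

    def __init__(self, message: str, last_estimate: float) -> None:
        super().__init__(message)
        self.last_estimate = last_estimate


@dataclass
class GenotypePanel:
    """Reference dosage matrix (n individuals x m SNPs, entries in [0, 2]).

    ``alleles[j]`` is ``(counted_allele, other_allele)`` for column ``j``.
    Missing dosages (NaN) are mean-imputed per SNP before correlation.
    """

    snp_ids: list[str]
    alleles: list[tuple[str, str]]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("dosage columns do not match snp_ids")
        if len(self.alleles) != len(self.snp_ids):
            raise ValueError("alleles do not match snp_ids")
        self._index = {s: j for j, s in enumerate(self.snp_ids)}
        if len(self._index) != len(self.snp_ids):
            raise ValueError("duplicate snp_id in panel")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def column_index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def column(self, snp_id: str) -> np.ndarray:
        """Mean-imputed dosage column for ``snp_id``."""
        x = self.dosages[:, self.column_index(snp_id)].copy()
        bad = ~np.isfinite(x)
        if bad.any():
            x[bad] = np.nanmean(x)
        return x

    def allele_freq(self, snp_id: str) -> float:
        """Frequency of the counted allele."""
        return float(np.mean(self.column(snp_id)) / 2.0)

    def subset(self, snp_ids: Sequence[str]) -> "GenotypePanel":
        idx = [self.column_index(s) for s in snp_ids]
        return GenotypePanel(
            snp_ids=list(snp_ids),
            alleles=[self.alleles[j] for j in idx],
            dosages=self.dosages[:, idx],
        )

    def corr_matrix(self, snp_ids: Sequence[str] | None = None) -> np.ndarray:
        """Pearson correlation matrix of (mean-imputed) dosage columns."""
        ids = list(snp_ids) if snp_ids is not None else self.snp_ids
        cols = np.column_stack([self.column(s) for s in ids])
        sd = cols.std(axis=0)
        if np.any(sd == 0):
            const = [ids[j] for j in np.nonzero(sd == 0)[0]]
            raise DegenerateLDError(f"constant dosage column(s): {', '.join(const)}")
        return np.corrcoef(cols, rowvar=False).reshape(len(ids), len(ids))


def ld_r(panel: GenotypePanel, snp_a: str, snp_b: str) -> float:
    """Signed genotypic correlation of the two counted alleles."""
    xa, xb = panel.column(snp_a), panel.column(snp_b)
    sa, sb = xa.std(), xb.std()
    if sa == 0 or sb == 0:
        raise DegenerateLDError(f"constant dosage column for {snp_a if sa == 0 else snp_b}")
    return float(np.corrcoef(xa, xb)[0, 1])


def ld_r2(panel: GenotypePanel, snp_a: str, snp_b: str) -> float:
    r = ld_r(panel, snp_a, snp_b)
    return r * r


def em_haplotype_freqs(
    panel: GenotypePanel,
    snp_a: str,
    snp_b: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> dict[str, float]:
    """Estimate two-locus haplotype frequencies by EM on unphased genotypes.

    Dosages are rounded to the nearest genotype in {0, 1, 2}. Returns the
    four frequencies keyed "AB", "Ab", "aB", "ab" where A/B denote the
    counted alleles at each locus. Starts from linkage equilibrium; stops
    when the AB-frequency update falls below ``tol``.
    """
    ga = np.clip(np.rint(panel.column(snp_a)), 0, 2).astype(int)
    gb = np.clip(np.rint(panel.column(snp_b)), 0, 2).astype(int)
    n = len(ga)
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.count_nonzero((ga == i) & (gb == j))

    p_a = ga.mean() / 2.0
    p_b = gb.mean() / 2.0
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise DegenerateLDError("monomorphic locus in D' computation")

    # only the double heterozygote is phase-ambiguous
    n_dh = counts[1, 1]
    # AB haplotypes contributed by phase-unambiguous genotype cells
    known_ab = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]

    p_ab = p_a * p_b  # freq of haplotype AB, start at equilibrium
    last = p_ab
    for _ in range(max_iter):
        p_Ab = p_a - p_ab
        p_aB = p_b - p_ab
        p_aa = 1.0 - p_a - p_b + p_ab
        num = p_ab * p_aa
        den = num + p_Ab * p_aB
        frac = 0.5 if den <= 0 else num / den
        new = (known_ab + n_dh * frac) / (2.0 * n)
        # keep the estimate inside the feasible simplex
        new = min(max(new, max(0.0, p_a + p_b - 1.0)), min(p_a, p_b))
        delta, p_ab, last = abs(new - p_ab), new, new
        if delta < tol:
            break
    else:
        raise EMConvergenceError(
            f"EM did not converge after {max_iter} iterations", last_estimate=last
        )
    return {
        "AB": p_ab,
        "Ab": p_a - p_ab,
        "aB": p_b - p_ab,
        "ab": 1.0 - p_a - p_b + p_ab,
    }


def ld_dprime(panel: GenotypePanel, snp_a: str, snp_b: str, **em_kwargs) -> float:
    """D' in [0, 1] from EM-estimated haplotype frequencies.

    D = p_AB - p_A p_B; D' = |D| / D_max with D_max the classical bound
    given the sign of D.
    """
    freqs = em_haplotype_freqs(panel, snp_a, snp_b, **em_kwargs)
    p_ab = freqs["AB"]
    p_a = p_ab + freqs["Ab"]
    p_b = p_ab + freqs["aB"]
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1.0 - p_b), (1.0 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1.0 - p_a) * (1.0 - p_b))
    if d_max <= 0:
        return 0.0
    return float(min(abs(d) / d_max, 1.0))


def write_panel(panel: GenotypePanel, dosage_path, meta_path) -> None:
    """Write the dosage matrix and its SNP-metadata sidecar (tab-delimited)."""
    pd.DataFrame(panel.dosages, columns=panel.snp_ids).to_csv(
        dosage_path, sep="\t", index=False, float_format="%.17g"
    )
    pd.DataFrame(
        {
            "SNP": panel.snp_ids,
            "COUNTED": [a for a, _ in panel.alleles],
            "OTHER": [b for _, b in panel.alleles],
        }
    ).to_csv(meta_path, sep="\t", index=False)


def read_panel(dosage_path, meta_path) -> GenotypePanel:
    dos = pd.read_csv(dosage_path, sep="\t")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if list(dos.columns) != list(meta["SNP"]):
        raise ValueError("dosage columns and metadata SNPs disagree")
    return GenotypePanel(
        snp_ids=list(meta["SNP"]),
        alleles=list(zip(meta["COUNTED"], meta["OTHER"])),
        dosages=dos.to_numpy(dtype=float),
    )


def read_plink_raw(path) -> GenotypePanel:
    """Import adapter for PLINK .raw-style exports.

    Expects a whitespace-delimited header of id columns (FID, IID, ...)
    followed by per-SNP dosage columns named ``rsid_countedallele``.
    """
    df = pd.read_csv(path, sep=r"\s+")
    id_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    snp_cols = [c for c in df.columns if c not in id_cols]
    snp_ids, alleles = [], []
    for c in snp_cols:
        if "_" in c:
            rsid, counted = c.rsplit("_", 1)
        else:
            rsid, counted = c, "N"
        snp_ids.append(rsid)
        alleles.append((counted, "N"))
    return GenotypePanel(
        snp_ids=snp_ids,
        alleles=alleles,
        dosages=df[snp_cols].to_numpy(dtype=float),
    )
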