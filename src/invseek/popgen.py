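"""Population- and quantitative-genetic analyses for the comb locus.

Three independent lines of evidence around a recombination-suppressing
inversion are modelled here:

* a sliding/tiled-window heterozygosity scan (H = 1 - sum p_i^2 per locus,
  averaged per window) that exposes the fixed haplotype of inversion
  homozygotes as a run of H = 0 windows;
* phase-known two-point linkage between markers and the comb trait in a
  carrier-sire backcross, with LOD = n[theta*log10(theta) +
  (1-theta)*log10(1-theta) + log10 2] at theta_hat = r/n;
* the breeding equilibrium that arises when single-combed (rr) parents are
  culled but homozygous Rose-comb (RR) sires are excluded by sperm
  competition: the r allele can neither fix nor disappear, and the flock
  settles at an allele frequency that keeps producing single-combed chicks
  every generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HetProfile",
    "LinkageResult",
    "BreedingParams",
    "EquilibriumResult",
    "heterozygosity",
    "locus_heterozygosity",
    "het_scan",
    "detect_sweep",
    "lod_score",
    "two_point_lod",
    "linkage_table",
    "rose_comb_equilibrium",
    "monte_carlo_flock",
]


# ---------------------------------------------------------- heterozygosity


def heterozygosity(freqs) -> float:
    """Expected heterozygosity H = 1 - sum p_i^2 for allele frequencies."""
    p = np.asarray(freqs, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must be non-negative and sum to 1")
    return float(1.0 - np.sum(p**2))


def locus_heterozygosity(genotypes: pd.DataFrame) -> np.ndarray:
    """Per-locus H from a loci x birds matrix coded 0/1/2 (NaN = missing)."""
    g = genotypes.to_numpy(dtype=float)
    p = np.nanmean(g, axis=1) / 2.0
    return 1.0 - p**2 - (1.0 - p) ** 2


@dataclass(frozen=True)
class HetProfile:
    """Windowed heterozygosity profile."""

    windows: pd.DataFrame  # start, end, n_loci, H


def het_scan(
    genotypes: pd.DataFrame,
    positions: np.ndarray,
    window: int = 500_000,
    stride: int | None = None,
    span: int | None = None,
) -> HetProfile:
    """Windowed mean of per-locus H (tiled by default, sliding via stride).

    Windows without loci report H = NaN.
    """
    positions = np.asarray(positions)
    if len(positions) != len(genotypes):
        raise ValueError("positions must align with genotype rows")
    stride = window if stride is None else stride
    span = int(positions.max()) + 1 if span is None else span
    h = locus_heterozygosity(genotypes)
    rows = []
    for start in range(0, span, stride):
        end = start + window
        mask = (positions >= start) & (positions < end)
        n = int(mask.sum())
        rows.append(
            {
                "start": start,
                "end": end,
                "n_loci": n,
                "H": float(np.mean(h[mask])) if n else np.nan,
            }
        )
    return HetProfile(windows=pd.DataFrame(rows))


def detect_sweep(
    cases: HetProfile, controls: HetProfile, tol: float = 0.0
) -> list[tuple[int, int]]:
    """Runs of windows fixed in cases (H <= tol) but variable in controls.

    Returns merged [start, end) intervals at window resolution.
    """
    cw, kw = cases.windows, controls.windows
    if not (cw["start"] == kw["start"]).all():
        raise ValueError("case and control profiles must share windows")
    hit = (
        (cw["n_loci"] > 0)
        & (kw["n_loci"] > 0)
        & (cw["H"] <= tol)
        & (kw["H"] > tol)
    ).to_numpy()
    intervals: list[tuple[int, int]] = []
    for i, flag in enumerate(hit):
        if not flag:
            continue
        start, end = int(cw["start"].iloc[i]), int(cw["end"].iloc[i])
        if intervals and intervals[-1][1] >= start:
            intervals[-1] = (intervals[-1][0], end)
        else:
            intervals.append((start, end))
    return intervals


# ---------------------------------------------------------------- linkage


@dataclass(frozen=True)
class LinkageResult:
    """Two-point linkage of one marker with the trait locus."""

    marker: str
    recombinants: int
    informative: int
    theta_hat: float
    lod: float


def lod_score(r: int, n: int) -> float:
    """Phase-known backcross LOD at the ML estimate theta_hat = r/n.

    LOD = n[t*log10 t + (1-t)*log10(1-t) + log10 2] with 0*log10(0) = 0;
    zero recombinants give n*log10(2), free recombination gives 0.
    """
    if n <= 0:
        raise ValueError("no informative meioses")
    t = r / n
    terms = 0.0
    if t > 0:
        terms += t * np.log10(t)
    if t < 1:
        terms += (1 - t) * np.log10(1 - t)
    return float(n * (terms + np.log10(2.0)))


def two_point_lod(
    pedigree: pd.DataFrame, marker: str, rose_label: str = "Rose"
) -> LinkageResult:
    """Marker-trait linkage over informative carrier-sire meioses.

    The design is phase-known: the carrier haplotype carries marker allele
    1, so a meiosis is recombinant when the transmitted allele disagrees
    with the phenotype.  Missing genotypes (coded -1) are excluded, so the
    informative count varies by marker.
    """
    alleles = pedigree[marker].to_numpy()
    rose = (pedigree["phenotype"] == rose_label).to_numpy()
    informative = alleles != -1
    n = int(informative.sum())
    if n == 0:
        return LinkageResult(marker, 0, 0, float("nan"), float("nan"))
    r = int(((alleles[informative] == 1) != rose[informative]).sum())
    return LinkageResult(marker, r, n, r / n, lod_score(r, n))


def linkage_table(pedigree: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Two-point results for a marker panel (one row per marker)."""
    rows = []
    for m in markers:
        res = two_point_lod(pedigree, m)
        rows.append(
            {
                "marker": m,
                "rec_frac": res.theta_hat,
                "lod": res.lod,
                "recombinants": res.recombinants,
                "informative": res.informative,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ equilibrium


@dataclass(frozen=True)
class BreedingParams:
    """Parameters of the Rose-comb flock breeding model.

    ``rr_sire_fertility`` is the relative competitive fertility of RR
    sires under flock mating (0 = fully outcompeted by sperm competition);
    ``cull_rr`` removes single-combed birds from both parental sexes.
    """

    rr_sire_fertility: float = 0.0
    cull_rr: bool = True
    q0: float = 0.5
    generations: int = 500
    tol: float = 1e-10
    flock_size: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rr_sire_fertility <= 1.0:
            raise ValueError("rr_sire_fertility must be in [0, 1]")
        if not 0.0 < self.q0 < 1.0:
            raise ValueError("q0 must be in (0, 1)")


@dataclass(frozen=True)
class EquilibriumResult:
    """Deterministic equilibrium of the breeding recursion."""

    q_star: float
    rr_fraction: float
    converged: bool
    generations: int
    trajectory: pd.DataFrame  # generation, q, rr_fraction


def _selection_weights(
    f: np.ndarray, params: BreedingParams
) -> tuple[np.ndarray, np.ndarray]:
    """(sire, dam) genotype weights after culling and sperm competition."""
    keep_rr = 0.0 if params.cull_rr else 1.0
    w_sire = np.array([f[0] * params.rr_sire_fertility, f[1], f[2] * keep_rr])
    w_dam = np.array([f[0], f[1], f[2] * keep_rr])
    if w_sire.sum() == 0 or w_dam.sum() == 0:
        raise ValueError("no eligible parents under these parameters")
    return w_sire, w_dam


def _gamete_freqs_from(f: np.ndarray, params: BreedingParams) -> tuple[float, float]:
    w_sire, w_dam = _selection_weights(f, params)
    q_s = (0.5 * w_sire[1] + w_sire[2]) / w_sire.sum()
    q_d = (0.5 * w_dam[1] + w_dam[2]) / w_dam.sum()
    return float(q_s), float(q_d)


def rose_comb_equilibrium(
    params: BreedingParams = BreedingParams(), parents: str = "hardy_weinberg"
) -> EquilibriumResult:
    """Iterate the deterministic breeding recursion to its fixed point.

    With rr culled from both sexes and RR sires fully excluded, dams
    contribute r gametes at q/(1+q) and sires at 1/2, so the offspring
    allele frequency follows q' = (1/2 + q/(1+q))/2; the reported
    equilibrium single-comb fraction is the rr offspring proportion
    q_s * q_d at the fixed point.

    ``parents`` selects the parental assumption: ``"hardy_weinberg"``
    (default) takes each generation's parents in Hardy-Weinberg
    proportions at the offspring allele frequency, giving the scalar
    recursion above; ``"genotype"`` tracks the actual offspring genotype
    fractions (which are not in Hardy-Weinberg proportions because sire
    and dam gamete frequencies differ) and settles at a slightly higher
    single-comb fraction.
    """
    if parents not in ("hardy_weinberg", "genotype"):
        raise ValueError("parents must be 'hardy_weinberg' or 'genotype'")
    q = params.q0
    f = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    rows = []
    converged = False
    gen = 0
    rr = float(f[2])
    for gen in range(1, params.generations + 1):
        q_s, q_d = _gamete_freqs_from(f, params)
        rr_next = q_s * q_d
        q_next = 0.5 * (q_s + q_d)
        if parents == "hardy_weinberg":
            f = np.array([(1 - q_next) ** 2, 2 * q_next * (1 - q_next), q_next**2])
        else:
            f = np.array(
                [
                    (1 - q_s) * (1 - q_d),
                    (1 - q_s) * q_d + q_s * (1 - q_d),
                    q_s * q_d,
                ]
            )
        rows.append({"generation": gen, "q": q_next, "rr_fraction": rr_next})
        done = abs(q_next - q) < params.tol and abs(rr_next - rr) < params.tol
        q, rr = q_next, rr_next
        if done:
            converged = True
            break
    return EquilibriumResult(
        q_star=q,
        rr_fraction=rr,
        converged=converged,
        generations=gen,
        trajectory=pd.DataFrame(rows),
    )


def monte_carlo_flock(
    params: BreedingParams = BreedingParams(),
    generations: int = 200,
    parents: str = "hardy_weinberg",
) -> pd.DataFrame:
    """Finite-flock stochastic counterpart of the deterministic recursion.

    Each generation, selection weights are computed from the realised
    genotype counts and ``flock_size`` offspring are drawn by multinomial
    sampling; ``parents`` matches the deterministic variant being checked
    (see :func:`rose_comb_equilibrium`).  The reported ``rr_offspring``
    column is the expected single-comb fraction q_s*q_d given that
    generation's parents; ``f_rr`` is the realised count fraction.
    """
    if parents not in ("hardy_weinberg", "genotype"):
        raise ValueError("parents must be 'hardy_weinberg' or 'genotype'")
    rng = np.random.default_rng(params.seed)
    n = params.flock_size
    q = params.q0
    counts = rng.multinomial(n, [(1 - q) ** 2, 2 * q * (1 - q), q * q])
    rows = []
    for gen in range(1, generations + 1):
        if parents == "hardy_weinberg":
            # parents assumed in HW proportions at the realised allele freq
            q_hat = (counts[1] + 2 * counts[2]) / (2 * n)
            f = np.array([(1 - q_hat) ** 2, 2 * q_hat * (1 - q_hat), q_hat**2])
        else:
            f = counts / n
        try:
            q_s, q_d = _gamete_freqs_from(f, params)
        except ValueError as exc:
            raise RuntimeError(f"no eligible parents at generation {gen}") from exc
        probs = [
            (1 - q_s) * (1 - q_d),
            (1 - q_s) * q_d + q_s * (1 - q_d),
            q_s * q_d,
        ]
        rr_expected = q_s * q_d
        counts = rng.multinomial(n, probs)
        rows.append(
            {
                "generation": gen,
                "f_RR": counts[0] / n,
                "f_Rr": counts[1] / n,
                "f_rr": counts[2] / n,
                "rr_offspring": rr_expected,
            }
        )
    return pd.DataFrame(rows)
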