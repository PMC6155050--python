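"""GWAS summary statistics: reading, instrument selection, clumping, harmonisation.

Summary statistics live in pandas DataFrames with canonical lower-case
columns ``snp, chrom, pos, ea, oa, eaf, beta, se, pval, n`` (``eaf`` and
``n`` optional).  Files are tab-separated with a header using the canonical
upper-case names ``SNP CHR POS EA OA EAF BETA SE P N``; a ``column_map``
re-binds arbitrary header names onto the canonical ones.

Harmonisation aligns an exposure and an outcome file onto the same effect
allele per SNP so that the per-SNP pair (gamma_hat, Gamma_hat) refers to
the same allele, resolving strand flips and palindromic (A/T, C/G)
ambiguity through effect-allele-frequency concordance, and finally orients
every retained record so the SNP-exposure effect is non-negative (the
orientation MR-Egger's intercept requires).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "REQUIRED_COLUMNS",
    "KEPT_ACTIONS",
    "SummaryDataError",
    "LDTable",
    "OverlapReport",
    "read_summary_stats",
    "write_summary_stats",
    "validate_summary_stats",
    "select_instruments",
    "clump",
    "find_proxy",
    "harmonise",
    "retained",
    "cross_trait_overlap",
]

#: canonical file header -> canonical frame column
CANONICAL_COLUMNS = {
    "SNP": "snp",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "ea",
    "OA": "oa",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
}

REQUIRED_COLUMNS = ("snp", "chrom", "pos", "ea", "oa", "beta", "se", "pval")

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# harmonisation actions; only the first four enter estimation
ACTION_KEPT = "kept"
ACTION_SIGN_FLIPPED = "sign_flipped"
ACTION_PALINDROMIC_ALIGNED = "palindromic_aligned"
ACTION_PROXY_SUBSTITUTED = "proxy_substituted"
ACTION_PALINDROMIC_DROPPED = "palindromic_dropped"
ACTION_MISSING_DROPPED = "missing_dropped"

KEPT_ACTIONS = frozenset(
    {ACTION_KEPT, ACTION_SIGN_FLIPPED, ACTION_PALINDROMIC_ALIGNED, ACTION_PROXY_SUBSTITUTED}
)


class SummaryDataError(ValueError):
    """Configuration or validation failure in a summary-statistics file."""


def _canonicalise(df: pd.DataFrame, column_map: dict[str, str] | None) -> pd.DataFrame:
    """Rename columns onto the canonical lower-case scheme."""
    rename: dict[str, str] = {}
    if column_map:
        # user map: {"BETA_COL_IN_FILE": "BETA"} or directly to canonical lower-case
        for src, dst in column_map.items():
            dst_canon = CANONICAL_COLUMNS.get(dst.upper(), dst.lower())
            rename[src] = dst_canon
    for col in df.columns:
        if col in rename:
            continue
        rename[col] = CANONICAL_COLUMNS.get(str(col).upper(), str(col).lower())
    return df.rename(columns=rename)


def validate_summary_stats(df: pd.DataFrame, *, on_invalid: str = "raise") -> pd.DataFrame:
    """Validate per-row invariants; rows are never silently dropped.

    Parameters
    ----------
    on_invalid : {"raise", "drop"}
        "raise" collects every violation and raises one error listing the
        offending line numbers (header = line 1, first data row = line 2);
        "drop" removes the rows with a warning carrying the same detail.
    """
    if on_invalid not in {"raise", "drop"}:
        raise ValueError(f"on_invalid must be 'raise' or 'drop', got {on_invalid!r}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryDataError(f"missing mandatory column(s): {', '.join(missing)}")

    df = df.copy()
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    if "n" not in df.columns:
        df["n"] = np.nan

    problems: list[str] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        if row["ea"] not in VALID_ALLELES or row["oa"] not in VALID_ALLELES:
            problems.append(f"line {line}: allele not in A/C/G/T ({row['ea']}/{row['oa']})")
            continue
        if row["ea"] == row["oa"]:
            problems.append(f"line {line}: effect and other allele identical")
        if not np.isfinite(row["se"]) or row["se"] <= 0:
            problems.append(f"line {line}: se must be > 0 (got {row['se']})")
        if not (0 < row["pval"] <= 1):
            problems.append(f"line {line}: pval must be in (0, 1] (got {row['pval']})")
        if np.isfinite(row["eaf"]) and not (0 <= row["eaf"] <= 1):
            problems.append(f"line {line}: eaf must be in [0, 1] (got {row['eaf']})")
        if not np.isfinite(row["beta"]):
            problems.append(f"line {line}: beta is not finite")

    if problems:
        detail = "; ".join(problems)
        if on_invalid == "raise":
            raise SummaryDataError(f"invalid summary-statistics rows: {detail}")
        warnings.warn(f"dropping invalid summary-statistics rows: {detail}")
        bad_lines = {int(p.split(":")[0].split()[1]) - 2 for p in problems}
        df = df.drop(index=list(bad_lines))
    return df.reset_index(drop=True)


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    *,
    sep: str = "\t",
    on_invalid: str = "raise",
) -> pd.DataFrame:
    """Read a delimited summary-statistics file into the canonical frame."""
    raw = pd.read_csv(path, sep=sep)
    df = _canonicalise(raw, column_map)
    return validate_summary_stats(df, on_invalid=on_invalid)


def write_summary_stats(df: pd.DataFrame, path, *, sep: str = "\t") -> None:
    """Write a canonical frame back to the TSV dialect ``read_summary_stats`` reads."""
    inv = {v: k for k, v in CANONICAL_COLUMNS.items()}
    out = df.rename(columns=inv)
    out.to_csv(path, sep=sep, index=False)


def select_instruments(assocs: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Keep associations with ``pval < p_threshold`` (input order preserved)."""
    if not 0 < p_threshold <= 1:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    out = assocs.loc[assocs["pval"] < p_threshold].reset_index(drop=True)
    if out.empty:
        warnings.warn(f"no SNP passes p < {p_threshold:g}; instrument is empty")
    return out


class LDTable:
    """Pairwise LD (r-squared) lookup, from an explicit table or a genotype panel.

    r² is symmetric, in [0, 1], and r²(x, x) = 1 by construction.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0 <= r2 <= 1:
            raise ValueError(f"r2 must be in [0, 1], got {r2}")
        self._r2[(min(a, b), max(a, b))] = float(r2)

    def get(self, a: str, b: str) -> float | None:
        """r²(a, b), or None if the pair is absent from the table."""
        if a == b:
            return 1.0
        return self._r2.get((min(a, b), max(a, b)))

    def known(self, snp: str) -> bool:
        return any(snp in key for key in self._r2)

    @classmethod
    def from_table(cls, path, *, sep: str = "\t") -> "LDTable":
        """Load a TSV of ``snp_a, snp_b, r2``."""
        df = pd.read_csv(path, sep=sep)
        df.columns = [c.lower() for c in df.columns]
        table = cls()
        for _, row in df.iterrows():
            table.set(str(row["snp_a"]), str(row["snp_b"]), float(row["r2"]))
        return table

    @classmethod
    def from_genotypes(cls, dosages: pd.DataFrame) -> "LDTable":
        """r² as squared Pearson correlation of additive dosages (samples x SNPs)."""
        corr = dosages.corr().to_numpy() ** 2
        snps = list(dosages.columns)
        table = cls()
        for i, a in enumerate(snps):
            for j in range(i + 1, len(snps)):
                r2 = corr[i, j]
                if np.isfinite(r2):
                    table.set(a, snps[j], float(min(r2, 1.0)))
        return table


def clump(
    assocs: pd.DataFrame,
    ld: LDTable | None,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
    *,
    missing_ld: str = "permissive",
) -> pd.DataFrame:
    """Greedy p-value clumping (PLINK style).

    Repeatedly take the remaining SNP with the smallest p-value as an index
    SNP and discard every remaining SNP on the same chromosome within
    ``window_kb`` whose r² with the index exceeds ``r2_max``.

    ``missing_ld``: "strict" errors when a within-window pair is absent from
    the LD table; "permissive" assumes r² = 0 with a warning.
    """
    if missing_ld not in {"strict", "permissive"}:
        raise ValueError(f"missing_ld must be 'strict' or 'permissive', got {missing_ld!r}")
    if assocs.empty:
        return assocs.copy()
    remaining = assocs.sort_values("pval", kind="mergesort").reset_index(drop=True)
    kept_rows = []
    missing_pairs: list[tuple[str, str]] = []
    while not remaining.empty:
        index_snp = remaining.iloc[0]
        kept_rows.append(index_snp)
        same_chr = remaining["chrom"].astype(str) == str(index_snp["chrom"])
        in_window = (remaining["pos"] - index_snp["pos"]).abs() <= window_kb * 1000
        drop = np.zeros(len(remaining), dtype=bool)
        drop[0] = True
        for i in np.nonzero((same_chr & in_window).to_numpy())[0]:
            if i == 0:
                continue
            other = remaining.iloc[i]
            r2 = ld.get(index_snp["snp"], other["snp"]) if ld is not None else None
            if r2 is None:
                if missing_ld == "strict":
                    raise SummaryDataError(
                        f"LD unknown for within-window pair ({index_snp['snp']}, {other['snp']})"
                    )
                missing_pairs.append((index_snp["snp"], other["snp"]))
                r2 = 0.0
            if r2 > r2_max:
                drop[i] = True
        remaining = remaining.loc[~drop].reset_index(drop=True)
    if missing_pairs:
        warnings.warn(
            f"{len(missing_pairs)} within-window SNP pair(s) absent from LD table; assumed r2=0"
        )
    out = pd.DataFrame(kept_rows).reset_index(drop=True)
    # restore input order among the survivors
    order = {s: i for i, s in enumerate(assocs["snp"])}
    return out.sort_values("snp", key=lambda s: s.map(order), kind="mergesort").reset_index(
        drop=True
    )


def find_proxy(
    target: str,
    outcome_assocs: pd.DataFrame,
    ld: LDTable,
    r2_min: float = 0.8,
) -> pd.Series | None:
    """Best available proxy for ``target`` among the outcome SNPs.

    Highest r² wins; ties break on smaller p-value, then lexicographic SNP id.
    Returns None when no candidate reaches ``r2_min`` or the target has no
    LD information at all.
    """
    if not ld.known(target):
        warnings.warn(f"proxy search: {target} absent from LD table")
        return None
    best = None
    best_key = None
    for _, row in outcome_assocs.iterrows():
        if row["snp"] == target:
            continue
        r2 = ld.get(target, row["snp"])
        if r2 is None or r2 < r2_min:
            continue
        key = (-r2, row["pval"], row["snp"])
        if best_key is None or key < best_key:
            best, best_key = row, key
    return best


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


@dataclass
class _HarmonisedRow:
    snp: str
    chrom: object
    pos: object
    ea: str
    oa: str
    gamma_hat: float
    sigma_x: float
    eaf_exposure: float
    Gamma_hat: float
    sigma_y: float
    eaf_outcome: float
    pval_exposure: float
    action: str
    proxy_snp: str = ""


def harmonise(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    maf_limit: float = 0.3,
    *,
    use_proxies: bool = False,
    ld: LDTable | None = None,
    proxy_r2_min: float = 0.8,
) -> pd.DataFrame:
    """Align exposure and outcome associations onto a shared effect allele.

    Per exposure SNP found in the outcome file:

    * identical allele pair -> kept as-is;
    * swapped alleles -> outcome beta sign flipped (eaf -> 1 - eaf);
    * strand complement of either of the above -> complemented first;
    * palindromic (A/T or C/G): retained only when both files report an
      effect-allele frequency, both minor-allele frequencies are below
      ``maf_limit`` and the two frequencies identify the same minor allele
      (sign flipped as needed), otherwise dropped;
    * absent from the outcome -> dropped, or substituted by the best LD
      proxy when ``use_proxies`` and an ``ld`` source are given;
    * incompatible allele pairs -> excluded with a warning.

    Finally every retained record is oriented so ``gamma_hat >= 0`` (the
    outcome beta and allele labels flipped in tandem), the convention the
    Egger intercept requires.  Rows that were dropped keep their action tag
    so the provenance of every instrument SNP is explicit.
    """
    for name, df in (("exposure", exposure), ("outcome", outcome)):
        dup = df.loc[df["snp"].duplicated(), "snp"]
        if not dup.empty:
            raise SummaryDataError(f"duplicate snp_id in {name} file: {', '.join(map(str, dup))}")

    out_by_snp = {row["snp"]: row for _, row in outcome.iterrows()}
    rows: list[_HarmonisedRow] = []
    incompatible: list[str] = []

    for _, exp in exposure.iterrows():
        snp = exp["snp"]
        proxy_used = ""
        if snp in out_by_snp:
            out = out_by_snp[snp]
        elif use_proxies and ld is not None:
            proxy = find_proxy(snp, outcome, ld, proxy_r2_min)
            if proxy is None:
                rows.append(_missing_row(exp))
                continue
            out, proxy_used = proxy, proxy["snp"]
        else:
            rows.append(_missing_row(exp))
            continue

        ea_x, oa_x = exp["ea"], exp["oa"]
        ea_y, oa_y = out["ea"], out["oa"]
        beta_y = float(out["beta"])
        eaf_y = float(out["eaf"]) if np.isfinite(out.get("eaf", np.nan)) else np.nan
        eaf_x = float(exp["eaf"]) if np.isfinite(exp.get("eaf", np.nan)) else np.nan

        if _is_palindromic(ea_x, oa_x):
            resolved = _resolve_palindrome(ea_x, oa_x, ea_y, oa_y, eaf_x, eaf_y, maf_limit)
            if resolved is None:
                rows.append(
                    _HarmonisedRow(
                        snp, exp["chrom"], exp["pos"], ea_x, oa_x,
                        float(exp["beta"]), float(exp["se"]), eaf_x,
                        np.nan, np.nan, np.nan, float(exp["pval"]),
                        ACTION_PALINDROMIC_DROPPED,
                    )
                )
                continue
            flip, action = resolved
        else:
            # try direct orientation, then strand complement
            pair = (ea_y, oa_y)
            comp_pair = (_COMPLEMENT.get(ea_y, "?"), _COMPLEMENT.get(oa_y, "?"))
            if pair == (ea_x, oa_x):
                flip, action = False, ACTION_KEPT
            elif pair == (oa_x, ea_x):
                flip, action = True, ACTION_SIGN_FLIPPED
            elif comp_pair == (ea_x, oa_x):
                flip, action = False, ACTION_KEPT
            elif comp_pair == (oa_x, ea_x):
                flip, action = True, ACTION_SIGN_FLIPPED
            else:
                incompatible.append(str(snp))
                continue

        if proxy_used:
            action = ACTION_PROXY_SUBSTITUTED
        if flip:
            beta_y = -beta_y
            if np.isfinite(eaf_y):
                eaf_y = 1.0 - eaf_y
        rows.append(
            _HarmonisedRow(
                snp, exp["chrom"], exp["pos"], ea_x, oa_x,
                float(exp["beta"]), float(exp["se"]), eaf_x,
                beta_y, float(out["se"]), eaf_y, float(exp["pval"]),
                action, proxy_used,
            )
        )

    if incompatible:
        warnings.warn(f"incompatible allele pairs dropped: {', '.join(incompatible)}")

    result = pd.DataFrame([vars(r) for r in rows])
    if result.empty:
        return result
    result = result.rename(columns={"sigma_x": "sigma_x", "sigma_y": "sigma_y"})

    # exposure-positive orientation for retained rows
    keep = result["action"].isin(KEPT_ACTIONS)
    neg = keep & (result["gamma_hat"] < 0)
    result.loc[neg, ["gamma_hat", "Gamma_hat"]] *= -1.0
    swap_ea = result.loc[neg, "ea"].copy()
    result.loc[neg, "ea"] = result.loc[neg, "oa"]
    result.loc[neg, "oa"] = swap_ea
    result.loc[neg, "eaf_exposure"] = 1.0 - result.loc[neg, "eaf_exposure"]
    result.loc[neg, "eaf_outcome"] = 1.0 - result.loc[neg, "eaf_outcome"]
    return result.reset_index(drop=True)


def _missing_row(exp: pd.Series) -> _HarmonisedRow:
    eaf_x = float(exp["eaf"]) if np.isfinite(exp.get("eaf", np.nan)) else np.nan
    return _HarmonisedRow(
        exp["snp"], exp["chrom"], exp["pos"], exp["ea"], exp["oa"],
        float(exp["beta"]), float(exp["se"]), eaf_x,
        np.nan, np.nan, np.nan, float(exp["pval"]),
        ACTION_MISSING_DROPPED,
    )


def _resolve_palindrome(
    ea_x: str, oa_x: str, ea_y: str, oa_y: str,
    eaf_x: float, eaf_y: float, maf_limit: float,
) -> tuple[bool, str] | None:
    """Frequency-based strand resolution for A/T and C/G SNPs.

    Returns (flip_sign, action) or None when the SNP must be dropped.
    """
    if {ea_y, oa_y} != {ea_x, oa_x}:
        return None
    if not (np.isfinite(eaf_x) and np.isfinite(eaf_y)):
        return None
    # frequency, in the outcome file, of the allele carrying the exposure's
    # effect-allele label
    q = eaf_y if ea_y == ea_x else 1.0 - eaf_y
    maf_x = min(eaf_x, 1.0 - eaf_x)
    maf_y = min(q, 1.0 - q)
    if maf_x >= maf_limit or maf_y >= maf_limit:
        return None
    if (eaf_x < 0.5) != (q < 0.5):
        # frequencies disagree on the minor allele: ambiguous, drop
        return None
    flip = ea_y != ea_x
    return flip, ACTION_PALINDROMIC_ALIGNED


def retained(harmonised: pd.DataFrame) -> pd.DataFrame:
    """Rows that enter estimation (action in KEPT_ACTIONS)."""
    if "action" not in harmonised.columns:
        return harmonised
    return harmonised.loc[harmonised["action"].isin(KEPT_ACTIONS)].reset_index(drop=True)


@dataclass
class OverlapReport:
    """Cross-trait overlap check of an instrument against another trait's GWAS."""

    table: pd.DataFrame = field(repr=False)
    n_flagged: int = 0
    p_threshold: float = 5e-8

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.n_flagged} of {len(self.table)} instrument SNP(s) associated with the "
            f"other trait at p < {self.p_threshold:g}"
        )


def cross_trait_overlap(
    instrument: pd.DataFrame,
    other_trait: pd.DataFrame,
    p_threshold: float = 5e-8,
) -> OverlapReport:
    """Report instrument SNPs that are also associated with another trait.

    Used to check that an instrument is specific to its exposure (e.g. that
    wellbeing SNPs are not genome-wide-significant depression SNPs).
    """
    other_p = dict(zip(other_trait["snp"], other_trait["pval"]))
    records = []
    for snp in instrument["snp"]:
        p = other_p.get(snp)
        records.append(
            {
                "snp": snp,
                "found": p is not None,
                "pval_other": p if p is not None else np.nan,
                "flagged": (p is not None) and (p < p_threshold),
            }
        )
    table = pd.DataFrame(records)
    return OverlapReport(table, int(table["flagged"].sum()), p_threshold)
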