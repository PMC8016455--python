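"""Reading and writing the formats the toolkit touches.

Summary statistics live in a plain :class:`pandas.DataFrame` with canonical
column names (``chr, pos, a0, a1, gamma_hat, se_gamma, n`` and optionally
``ncase, ncontrol, freq``).  Genotypes are held in :class:`GenotypePanel`
(dosage matrix with NaN for missing calls) and read/written as PLINK 1
bed/bim/fam.  The on-disk sparse LD container is a versioned ``.npz`` bundle
storing the CSR arrays at full double precision together with the variant
metadata and the window size used to build it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ("chr", "pos", "a0", "a1", "gamma_hat", "se_gamma", "n")

#: allele pairs whose strand cannot be resolved without frequencies
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_LD_FORMAT_VERSION = "ldx-1"


def _normalize_chr(values) -> pd.Series:
    """Chromosome labels as strings with any 'chr' prefix stripped."""
    s = pd.Series(values).astype(str).str.replace("^chr", "", regex=True)
    return s


@dataclass
class GenotypePanel:
    """Hard-call dosage matrix (individuals x variants) with variant metadata.

    Dosages count copies of the effect allele ``a1`` (the first-listed bim
    allele); missing calls are NaN.
    """

    dosages: np.ndarray
    variants: pd.DataFrame  # columns chr, pos, a0, a1 (and optionally id)
    samples: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"dosage columns ({self.dosages.shape[1]}) do not match "
                f"variant metadata rows ({len(self.variants)})"
            )
        self.variants = self.variants.reset_index(drop=True)
        self.variants["chr"] = _normalize_chr(self.variants["chr"]).values
        if not self.samples:
            self.samples = [f"id_{i}" for i in range(self.dosages.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_variants(self) -> int:
        return self.dosages.shape[1]

    def sd(self, ddof: int = 1) -> np.ndarray:
        """Per-variant dosage standard deviation, missing entries excluded."""
        with np.errstate(invalid="ignore"):
            return np.nanstd(self.dosages, axis=0, ddof=ddof)

    def monomorphic(self) -> np.ndarray:
        sd = self.sd(ddof=0)
        return (sd == 0) | ~np.isfinite(sd)


def validate_sumstats(ss: pd.DataFrame, drop_invalid: bool = True) -> pd.DataFrame:
    """Enforce the summary-statistics invariants.

    Rows with non-positive standard errors or sample sizes, identical
    alleles, or duplicated (chr, pos, a0, a1) keys are dropped (counts
    logged) when ``drop_invalid`` is set, else a ValueError is raised.
    """
    missing = [c for c in SUMSTATS_COLUMNS if c not in ss.columns]
    if missing:
        raise ValueError(f"summary statistics missing required columns: {missing}")
    ss = ss.copy()
    ss["chr"] = _normalize_chr(ss["chr"]).values
    for c in ("a0", "a1"):
        ss[c] = ss[c].astype(str).str.upper()
    bad = (
        ~(ss["se_gamma"] > 0)
        | ~(ss["n"] > 0)
        | (ss["a0"] == ss["a1"])
        | ss[["gamma_hat", "se_gamma", "n"]].isna().any(axis=1)
    )
    dup = ss.duplicated(subset=["chr", "pos", "a0", "a1"], keep="first")
    bad = bad | dup
    if bad.any():
        if not drop_invalid:
            raise ValueError(f"{int(bad.sum())} rows violate sumstats invariants")
        logger.info("dropping %d summary-statistics rows violating invariants", int(bad.sum()))
        ss = ss.loc[~bad]
    return ss.reset_index(drop=True)


def read_sumstats(path, column_map: dict | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited summary-statistics table into canonical form.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"gamma_hat": "beta", "se_gamma": "beta_se"}``.  When ``n`` is absent
    but case/control counts are present, the per-variant effective sample
    size 4 / (1/ncase + 1/ncontrol) is filled in.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+")
    if df.empty:
        raise ValueError(f"empty summary-statistics file: {path}")
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise ValueError(f"mapped column(s) not found in {path}: {missing}")
        df = df.rename(columns={src: dst for dst, src in column_map.items()})
    if "n" not in df.columns:
        if {"ncase", "ncontrol"}.issubset(df.columns):
            # local import to avoid a module cycle
            from .prep import effective_sample_size

            df["n"] = effective_sample_size(
                df["ncase"].to_numpy(float), df["ncontrol"].to_numpy(float)
            )
        else:
            raise ValueError("summary statistics need either 'n' or 'ncase'+'ncontrol'")
    return validate_sumstats(df)


def write_sumstats(ss: pd.DataFrame, path) -> None:
    ss.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK 1 bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of the first-listed (counted) bim allele
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink_bed(prefix) -> GenotypePanel:
    """Read a variant-major PLINK 1 fileset into a GenotypePanel."""
    prefix = str(prefix)
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chr", "id", "cm", "pos", "a1", "a0"],
        dtype={"chr": str, "a1": str, "a0": str},
    )
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not a variant-major bed file)")
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise ValueError(
            f"{prefix}.bed has {len(raw)} bytes, expected {expected} for "
            f"{n} samples x {m} variants"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
    # unpack 2-bit codes, low bits first within each byte
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # individuals x variants
    variants = bim[["chr", "pos", "a0", "a1", "id"]].copy()
    samples = fam.iloc[:, 1].astype(str).tolist()
    return GenotypePanel(dosages=dosages, variants=variants, samples=samples)


def write_plink_bed(panel: GenotypePanel, prefix) -> None:
    """Write a GenotypePanel as a variant-major PLINK 1 fileset."""
    prefix = str(prefix)
    n, m = panel.dosages.shape
    dos = panel.dosages
    # dosage -> 2-bit code (counting a1 copies): 2->00, missing->01, 1->10, 0->11
    codes = np.full((m, n), 0b01, dtype=np.uint8)
    dt = dos.T
    codes[dt == 2] = 0b00
    codes[dt == 1] = 0b10
    codes[dt == 0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    packed = np.zeros((m, codes.shape[1] // 4), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    v = panel.variants
    ids = v["id"] if "id" in v.columns else [f"v{i}" for i in range(m)]
    bim = pd.DataFrame(
        {"chr": v["chr"], "id": ids, "cm": 0, "pos": v["pos"], "a1": v["a1"], "a0": v["a0"]}
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.samples,
            "iid": panel.samples,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


def read_genetic_map(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a 3-column (chr, pos_bp, pos_cM) delimited map.

    Returns per-chromosome ``(pos_bp, pos_cM)`` arrays sorted by bp; the bp
    positions must be strictly increasing and the cM positions
    non-decreasing within each chromosome.
    """
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.lower() for c in df.columns]
    cols = list(df.columns[:3])
    df = df.rename(columns=dict(zip(cols, ["chr", "pos_bp", "pos_cm"])))
    df["chr"] = _normalize_chr(df["chr"]).values
    out = {}
    for chrom, grp in df.groupby("chr", sort=False):
        grp = grp.sort_values("pos_bp")
        bp = grp["pos_bp"].to_numpy(float)
        cm = grp["pos_cm"].to_numpy(float)
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"genetic map: non-increasing bp positions on chr {chrom}")
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"genetic map: decreasing cM positions on chr {chrom}")
        out[str(chrom)] = (bp, cm)
    return out


def write_genetic_map(gmap: dict, path) -> None:
    rows = []
    for chrom, (bp, cm) in gmap.items():
        for b, c in zip(bp, cm):
            rows.append((chrom, int(b), c))
    pd.DataFrame(rows, columns=["chr", "pos_bp", "pos_cm"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant matching
# ---------------------------------------------------------------------------


def match_variants(
    ss: pd.DataFrame,
    panel_meta: pd.DataFrame,
    remove_ambiguous: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Match summary statistics to reference-panel variants on (chr, pos).

    Same-order alleles are kept as-is; swapped alleles (a0<->a1) are kept
    with the sign of ``gamma_hat`` flipped (and ``freq`` complemented when
    present).  Strand-ambiguous pairs (A/T, C/G) are removed under the
    default policy.  Returns the matched table in panel order together with
    the column indices into the panel.
    """
    ss = validate_sumstats(ss)
    meta = panel_meta.reset_index(drop=True).copy()
    meta["chr"] = _normalize_chr(meta["chr"]).values
    meta["_col"] = np.arange(len(meta))
    merged = ss.merge(
        meta[["chr", "pos", "a0", "a1", "_col"]].rename(
            columns={"a0": "a0_ref", "a1": "a1_ref"}
        ),
        on=["chr", "pos"],
        how="inner",
    )
    n_unmatched = len(ss) - merged["_col"].nunique() if len(merged) else len(ss)
    same = (merged["a0"] == merged["a0_ref"]) & (merged["a1"] == merged["a1_ref"])
    swapped = (merged["a0"] == merged["a1_ref"]) & (merged["a1"] == merged["a0_ref"])
    ambiguous = [
        (a0, a1) in AMBIGUOUS_PAIRS for a0, a1 in zip(merged["a0"], merged["a1"])
    ]
    ambiguous = np.asarray(ambiguous, dtype=bool)
    keep = (same | swapped).to_numpy()
    n_allele_mismatch = int((~keep).sum())
    if remove_ambiguous:
        keep &= ~ambiguous
    matched = merged.loc[keep].copy()
    flip = swapped.to_numpy()[keep]
    matched.loc[flip, "gamma_hat"] = -matched.loc[flip, "gamma_hat"]
    if "freq" in matched.columns:
        matched.loc[flip, "freq"] = 1.0 - matched.loc[flip, "freq"]
    # report panel-orientation alleles (a1 = counted/effect allele of the panel)
    matched["a0"] = matched["a0_ref"]
    matched["a1"] = matched["a1_ref"]
    matched = matched.drop(columns=["a0_ref", "a1_ref"]).sort_values("_col")
    logger.info(
        "match_variants: %d kept (%d sign-flipped), %d unmatched positions, "
        "%d allele mismatches, %d strand-ambiguous removed",
        len(matched), int(flip.sum()), n_unmatched, n_allele_mismatch,
        int((ambiguous & (same | swapped).to_numpy()).sum()) if remove_ambiguous else 0,
    )
    if matched.empty:
        raise ValueError("no variants could be matched between sumstats and the panel")
    cols = matched.pop("_col").to_numpy()
    return matched.reset_index(drop=True), cols


# ---------------------------------------------------------------------------
# On-disk sparse LD
# ---------------------------------------------------------------------------


def save_ld(ld, path) -> None:
    """Save an LDMatrix as a versioned npz bundle (lossless)."""
    R = ld.R.tocsr()
    # write through a file handle so numpy does not append an .npz suffix
    with open(path, "wb") as fh:
        _save_ld_npz(fh, ld, R)


def _save_ld_npz(fh, ld, R):
    np.savez(
        fh,
        version=np.array(_LD_FORMAT_VERSION),
        indptr=R.indptr,
        indices=R.indices,
        data=R.data.astype(np.float64),
        shape=np.array(R.shape),
        genpos=np.asarray(ld.genpos, dtype=np.float64),
        window_cm=np.array(float(ld.window_cM)),
        chr=ld.variants["chr"].to_numpy(str),
        pos=ld.variants["pos"].to_numpy(np.int64),
        a0=ld.variants["a0"].to_numpy(str),
        a1=ld.variants["a1"].to_numpy(str),
        monomorphic=np.asarray(ld.monomorphic, dtype=bool),
    )


def load_ld(path):
    from .ld import LDMatrix

    with np.load(path, allow_pickle=False) as z:
        version = str(z["version"])
        if version != _LD_FORMAT_VERSION:
            raise ValueError(
                f"LD container version mismatch: found {version!r}, "
                f"expected {_LD_FORMAT_VERSION!r}"
            )
        R = sp.csr_matrix((z["data"], z["indices"], z["indptr"]), shape=tuple(z["shape"]))
        variants = pd.DataFrame(
            {"chr": z["chr"].astype(str), "pos": z["pos"], "a0": z["a0"].astype(str),
             "a1": z["a1"].astype(str)}
        )
        return LDMatrix(
            R=R,
            genpos=z["genpos"],
            variants=variants,
            window_cM=float(z["window_cm"]),
            monomorphic=z["monomorphic"],
        )
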