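"""File I/O: PLINK 1 binary genotypes, score files, and TSV conventions.

All tabular output is tab-separated UTF-8 with ``NA`` as the missing token,
matching the conventions of phenotype/covariate files consumed by standard
genome-analysis toolkits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # missing-dosage code in integer genotype matrices

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

#: 2-bit PLINK codes -> A1 dosage. 00 = hom A1 (2), 01 = missing,
#: 10 = het (1), 11 = hom A2 (0).
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


@dataclasses.dataclass
class GenotypeMatrix:
    """Sample-by-variant A1 dosage matrix with metadata.

    ``X`` is int8 with entries in {0, 1, 2} and :data:`MISSING` for no-calls.
    ``variants`` carries at least ``id, chrom, pos, a1, a2``; ``samples``
    carries ``fid, iid`` and optionally ``population``.
    """

    X: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variants(self) -> int:
        return self.X.shape[1]

    def dosages(self, impute_freq: np.ndarray | None = None) -> np.ndarray:
        """Float copy of ``X`` with missing entries as NaN or mean-imputed.

        ``impute_freq`` gives per-variant A1 allele frequencies; missing
        dosages become ``2 * freq``.
        """
        D = self.X.astype(np.float64)
        miss = self.X == MISSING
        if impute_freq is None:
            D[miss] = np.nan
        else:
            D[miss] = (2.0 * np.asarray(impute_freq))[np.nonzero(miss)[1]]
        return D

    def allele_frequencies(self) -> np.ndarray:
        """Per-variant A1 frequency over non-missing calls."""
        D = self.X.astype(np.float64)
        miss = self.X == MISSING
        D[miss] = 0.0
        n_called = (~miss).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return D.sum(axis=0) / (2.0 * n_called)


class PlinkFormatError(ValueError):
    """Malformed or unsupported PLINK binary input."""


def _sib(prefix, ext):
    return Path(str(prefix) + ext)


def read_plink_bed(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 ``.bed/.bim/.fam`` triplet (SNP-major only).

    Dosages count the A1 allele (first allele column of the .bim file).
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        _sib(prefix, ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        _sib(prefix, ".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(_sib(prefix, ".bed"), dtype=np.uint8)
    if raw[:2].tobytes() != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{prefix}.bed: sample-major layout is not supported"
        )
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_variant * m:
        raise PlinkFormatError(
            f"{prefix}.bed: truncated (expected {bytes_per_variant * m} "
            f"data bytes, found {body.size})"
        )
    blocks = body.reshape(m, bytes_per_variant)
    # unpack 2-bit fields, sample i at bit offset 2*(i % 4), little-endian
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    X = _CODE_TO_DOSAGE[codes].T.copy()
    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(X=X, variants=variants, samples=fam[["fid", "iid"]].copy())


def write_plink_bed(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a SNP-major PLINK 1 ``.bed/.bim/.fam`` triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.n_samples, G.n_variants

    v = G.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"] if "chrom" in v else 1,
            "id": v["id"],
            "cm": 0,
            "pos": v["pos"] if "pos" in v else np.arange(1, m + 1),
            "a1": v["a1"] if "a1" in v else "A",
            "a2": v["a2"] if "a2" in v else "G",
        }
    )
    bim.to_csv(_sib(prefix, ".bim"), sep="\t", header=False, index=False)
    s = G.samples
    fam = pd.DataFrame(
        {
            "fid": s["fid"] if "fid" in s else s["iid"],
            "iid": s["iid"],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam.to_csv(_sib(prefix, ".fam"), sep="\t", header=False, index=False)

    code_lut = np.empty(256, dtype=np.uint8)  # int8 dosage -> 2-bit code
    for dosage, code in _DOSAGE_TO_CODE.items():
        code_lut[dosage % 256] = code
    codes = code_lut[G.X.T.astype(np.uint8)]
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.full((m, pad), _DOSAGE_TO_CODE[0], dtype=np.uint8)], axis=1
        )
    codes = codes.reshape(m, -1, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes << shifts).sum(axis=2, dtype=np.uint16).astype(np.uint8)
    with open(_sib(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        packed.tofile(fh)


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a TSV with the package-wide NA and decimal conventions."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=float_format)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_score_file(model, path: str | Path) -> None:
    """Write a PRS model as an ID/A1/BETA score TSV plus a JSON sidecar.

    The TSV is consumable by standard genome-analysis toolkits' --score
    facilities; the extra A1_FREQ column records training allele frequencies
    for missing-dosage imputation. Covariate coefficients, the intercept,
    the chosen λ, and the family go to ``<path>.json``.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "ID": model.variant_ids,
            "A1": model.effect_allele,
            "BETA": model.weights,
            "A1_FREQ": model.train_freq,
        }
    )
    write_tsv(df, path, float_format="%.17g")
    write_json(
        {
            "covariate_names": list(model.covariate_names),
            "covariate_coefs": list(map(float, model.covariate_coefs)),
            "intercept": float(model.intercept),
            "lambda": float(model.lam),
            "family": model.family,
        },
        Path(str(path) + ".json"),
    )


def read_score_file(path: str | Path):
    """Read a score TSV (and sidecar, if present) back into a PRSModel."""
    from .prs_fit import PRSModel

    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    freq = (
        df["A1_FREQ"].to_numpy(dtype=float)
        if "A1_FREQ" in df
        else np.full(len(df), 0.5)
    )
    return PRSModel(
        variant_ids=df["ID"].astype(str).tolist(),
        effect_allele=df["A1"].astype(str).tolist(),
        weights=df["BETA"].to_numpy(dtype=float),
        train_freq=freq,
        covariate_names=meta.get("covariate_names", []),
        covariate_coefs=np.asarray(meta.get("covariate_coefs", []), dtype=float),
        intercept=float(meta.get("intercept", 0.0)),
        lam=float(meta.get("lambda", np.nan)),
        family=meta.get("family", "gaussian"),
    )
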