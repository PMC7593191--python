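"""Readers and writers: GenePop genotypes, CSV metadata/hierarchy/Q-matrix,
labeled distance matrices, cognate catalogs, YAML configs.

GenePop files follow the 4.x conventions: a title line, one locus name per
line (or a single comma-separated line), ``POP`` separators, and per
individual an identifier, a comma, and one 2x2- or 2x3-digit allele string
per locus with all-zero codes meaning a missing call.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    ClusterAssignment,
    CognateCatalog,
    DataModelError,
    GenotypeDataset,
    LabeledMatrix,
    LanguageHierarchy,
    PopulationMetadata,
    WordTerm,
)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def read_genepop(path: str | os.PathLike) -> GenotypeDataset:
    """Parse a GenePop 4.x file into a :class:`GenotypeDataset`.

    Populations are kept in file order and named after the identifier of
    their first individual.  Allele code ``00``/``000`` is a missing gene;
    a half-missing diploid call is rejected.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file (line 1)")

    loci: list[str] = []
    i = 1  # skip title line
    while i < len(lines):
        line = lines[i].strip()
        if line.upper() in {"POP"}:
            break
        if not line:
            i += 1
            continue
        if "," in line:
            loci.extend(tok.strip() for tok in line.split(",") if tok.strip())
        else:
            loci.append(line)
        i += 1
    if not loci:
        raise ParseError(f"{path}: no locus names before first POP (line {i + 1})")
    if i >= len(lines):
        raise ParseError(f"{path}: malformed header, no POP separator found")

    calls: dict[str, list[list[tuple[str, str] | None]]] = {}
    current: list[list[tuple[str, str] | None]] | None = None
    width: int | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            current = None
            continue
        if "," not in line:
            raise ParseError(f"{path}: line {lineno + 1}: missing ',' after identifier")
        ident, _, geno = line.partition(",")
        ident = ident.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"{path}: line {lineno + 1}: {len(tokens)} genotypes for "
                f"{len(loci)} loci"
            )
        row: list[tuple[str, str] | None] = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ParseError(
                    f"{path}: line {lineno + 1}: allele string {tok!r} must be "
                    "4 or 6 digits"
                )
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise ParseError(
                    f"{path}: line {lineno + 1}: mixed 2- and 3-digit allele codes"
                )
            a, b = tok[:w], tok[w:]
            zero = "0" * w
            if a == zero and b == zero:
                row.append(None)
            elif zero in (a, b):
                raise ParseError(
                    f"{path}: line {lineno + 1}: half-missing call {tok!r}"
                )
            else:
                row.append((a, b))
        if current is None:
            if ident in calls:
                raise ParseError(
                    f"{path}: line {lineno + 1}: duplicate population label {ident!r}"
                )
            current = calls.setdefault(ident, [])
        current.append(row)
    if not calls:
        raise ParseError(f"{path}: no individuals found")
    return GenotypeDataset.from_calls(loci, calls)


def write_genepop(dataset: GenotypeDataset, path: str | os.PathLike, title: str = "bcpg export") -> None:
    """Write canonical GenePop: 3-digit codes, one locus name per line."""
    width = 3
    for names in dataset.allele_names:
        for tok in names:
            if len(tok) > width or not tok.isdigit():
                raise DataModelError(
                    f"allele token {tok!r} not expressible as a {width}-digit code"
                )
    out = [title]
    out.extend(dataset.loci)
    for pop in dataset.populations:
        out.append("POP")
        for ind in dataset.calls_for(pop):
            toks = []
            for call in ind:
                if call is None:
                    toks.append("000000")
                else:
                    toks.append(call[0].zfill(width) + call[1].zfill(width))
            out.append(f"{pop} , " + " ".join(toks))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Metadata / hierarchy
# ---------------------------------------------------------------------------

def read_hierarchy(path: str | os.PathLike) -> LanguageHierarchy:
    """CSV with columns language, subgroup (may be empty), family, phylum."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"language", "family", "phylum"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: hierarchy needs columns {sorted(required)}")
    mapping = {}
    for _, row in df.iterrows():
        sub = row.get("subgroup", "") or None
        mapping[row["language"]] = (sub, row["family"], row["phylum"])
    return LanguageHierarchy(mapping)


def write_hierarchy(h: LanguageHierarchy, path: str | os.PathLike) -> None:
    h.to_frame().to_csv(path, index=False)


def read_metadata(
    path: str | os.PathLike, hierarchy: LanguageHierarchy
) -> list[PopulationMetadata]:
    """Read site metadata and validate its languages against the hierarchy.

    Expected columns: site, lat, lon, country, languages (``;``-separated),
    optional word_terms (``;``-separated ``term:class:cognate_set`` entries).
    Duplicate site rows are an error, as are out-of-range coordinates.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"site", "lat", "lon", "country", "languages"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: metadata needs columns {sorted(required)}")
    if df["site"].duplicated().any():
        dups = df.loc[df["site"].duplicated(), "site"].tolist()
        raise ParseError(f"{path}: duplicate sites {dups}")
    out = []
    bad_lang_rows = []
    for rownum, row in df.iterrows():
        langs = frozenset(tok.strip() for tok in row["languages"].split(";") if tok.strip())
        unknown = [l for l in sorted(langs) if l not in hierarchy]
        if unknown:
            bad_lang_rows.append((rownum + 2, row["site"], unknown))
            continue
        terms = []
        for entry in row.get("word_terms", "").split(";"):
            entry = entry.strip()
            if not entry:
                continue
            parts = entry.split(":")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: row {rownum + 2}: word term {entry!r} not "
                    "'term:class:cognate_set'"
                )
            terms.append(WordTerm(*parts))
        try:
            out.append(
                PopulationMetadata(
                    site=row["site"],
                    latitude=float(row["lat"]),
                    longitude=float(row["lon"]),
                    country=row["country"],
                    languages=langs,
                    word_terms=tuple(terms),
                )
            )
        except (DataModelError, ValueError) as exc:
            raise ParseError(f"{path}: row {rownum + 2}: {exc}") from exc
    if bad_lang_rows:
        desc = "; ".join(
            f"row {r} ({site}): {langs}" for r, site, langs in bad_lang_rows
        )
        raise ParseError(f"{path}: unknown languages — {desc}")
    return out


def write_metadata(metadata: Sequence[PopulationMetadata], path: str | os.PathLike) -> None:
    rows = []
    for m in metadata:
        rows.append(
            {
                "site": m.site,
                "lat": m.latitude,
                "lon": m.longitude,
                "country": m.country,
                "languages": ";".join(sorted(m.languages)),
                "word_terms": ";".join(
                    f"{t.term}:{t.word_class}:{t.cognate_set}" for t in m.word_terms
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Q-matrix / labeled matrices / cognates
# ---------------------------------------------------------------------------

def read_qmatrix(path: str | os.PathLike, threshold: float = 0.7) -> ClusterAssignment:
    """CSV of per-population mean membership rows: site, Q1..QK."""
    df = pd.read_csv(path)
    if "site" not in df.columns:
        raise ParseError(f"{path}: Q-matrix needs a 'site' column")
    qcols = [c for c in df.columns if c != "site"]
    if len(qcols) < 2:
        raise ParseError(f"{path}: Q-matrix needs at least 2 cluster columns")
    q = df[qcols].to_numpy(dtype=float)
    try:
        return ClusterAssignment(df["site"].astype(str).tolist(), q, threshold)
    except DataModelError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_matrix(m: LabeledMatrix, path: str | os.PathLike) -> None:
    m.to_frame().to_csv(path, float_format="%.12g")


def read_matrix(path: str | os.PathLike, kind: str = "derived") -> LabeledMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = [str(l) for l in df.index]
    if labels != [str(c) for c in df.columns]:
        raise ParseError(f"{path}: row and column labels differ")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ParseError(f"{path}: matrix contains missing cells")
    try:
        return LabeledMatrix(labels, values, kind)
    except DataModelError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_cognates(path: str | os.PathLike) -> CognateCatalog:
    """Wide CSV: 'site' column then one 0/1 presence column per cognate set."""
    df = pd.read_csv(path)
    if "site" not in df.columns:
        raise ParseError(f"{path}: cognate table needs a 'site' column")
    df = df.set_index("site")
    if df.empty or not len(df.columns):
        raise ParseError(f"{path}: cognate table has no cognate columns")
    return CognateCatalog(df.astype(int).astype(bool))


def write_cognates(cat: CognateCatalog, path: str | os.PathLike) -> None:
    cat.presence.astype(int).rename_axis("site").to_csv(path)


# ---------------------------------------------------------------------------
# YAML helpers
# ---------------------------------------------------------------------------

def read_yaml(path: str | os.PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_yaml(obj: dict, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
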