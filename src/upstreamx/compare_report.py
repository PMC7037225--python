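"""Comparative logic over master-regulator tables from different treatments:
direction-matched overlaps, the regulator common to every treatment, two-set
Venn counts per direction, and functional-category annotation tallies.

The package ships the published regulator lists for the LDL treatment arms
(naturally occurring, desialylated, acetylated, oxidized LDL) and their
functional annotations (innate immunity / lipid metabolism / phagocytosis)
as TSV fixtures, loadable via :func:`load_table3` / :func:`load_table5`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

VALID_FLAGS = {"+", "-", "?"}


@dataclass
class RegulatorTable:
    """Up- and down-regulated master-regulator gene symbols for one
    treatment. Symbols are uppercased and deduplicated, order preserved."""

    treatment: str
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.up = _normalize_symbols(self.up)
        self.down = _normalize_symbols(self.down)
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(
                f"{self.treatment}: genes in both directions: "
                f"{sorted(overlap)}"
            )

    @property
    def total(self) -> int:
        return len(self.up) + len(self.down)


def _normalize_symbols(symbols: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for s in symbols:
        u = s.strip().upper()
        if u and u not in seen:
            seen.add(u)
            out.append(u)
    return out


@dataclass
class AnnotationTable:
    """gene symbol -> {category -> '+', '-' or '?'}."""

    rows: dict[str, dict[str, str]]

    CATEGORIES = ("innate_immunity", "lipid_metabolism", "phagocytosis")

    def __post_init__(self) -> None:
        for gene, flags in self.rows.items():
            for cat in self.CATEGORIES:
                flag = flags.get(cat)
                if flag not in VALID_FLAGS:
                    raise ValueError(
                        f"{gene}: bad flag {flag!r} for {cat} "
                        f"(expected one of {sorted(VALID_FLAGS)})"
                    )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def read_regulator_tables(path: str | Path) -> dict[str, RegulatorTable]:
    """Read a TSV with columns treatment, direction, gene."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:3]) != ["treatment", "direction", "gene"]:
        raise ValueError(
            f"{path}: expected header 'treatment\\tdirection\\tgene'"
        )
    tables: dict[str, RegulatorTable] = {}
    for treatment, sub in df.groupby("treatment", sort=False):
        up = sub.loc[sub["direction"] == "up", "gene"].tolist()
        down = sub.loc[sub["direction"] == "down", "gene"].tolist()
        bad = set(sub["direction"]) - {"up", "down"}
        if bad:
            raise ValueError(f"{path}: bad direction value {sorted(bad)}")
        tables[str(treatment)] = RegulatorTable(str(treatment), up, down)
    return tables


def read_annotations(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    rows = {
        str(r["gene"]).upper(): {
            cat: str(r[cat]) for cat in AnnotationTable.CATEGORIES
        }
        for _, r in df.iterrows()
    }
    return AnnotationTable(rows)


def _fixture(name: str) -> Path:
    return Path(str(resources.files("upstreamx").joinpath("data", name)))


def load_table3() -> dict[str, RegulatorTable]:
    """Published LDL-treatment master-regulator lists (packaged fixture)."""
    return read_regulator_tables(_fixture("table3_regulators.tsv"))


def load_table5() -> AnnotationTable:
    """Published functional annotations of the top regulators (fixture)."""
    return read_annotations(_fixture("table5_annotations.tsv"))


# ---------------------------------------------------------------------------
# Set arithmetic
# ---------------------------------------------------------------------------

def match_directional(a: RegulatorTable, b: RegulatorTable,
                      ) -> tuple[set[str], set[str], int, int]:
    """Direction-matched overlap: a gene matches only when it appears with
    the same direction in both tables. Returns
    (matched_up, matched_down, n_matched, n_b_total)."""
    matched_up = set(a.up) & set(b.up)
    matched_down = set(a.down) & set(b.down)
    return matched_up, matched_down, len(matched_up) + len(matched_down), b.total


def common_to_all(tables: list[RegulatorTable],
                  reference: RegulatorTable) -> set[str]:
    """Genes matched (direction agreeing with the reference) in every
    listed table."""
    if len(tables) < 1:
        raise ValueError("need at least one comparison table")
    common: set[str] | None = None
    for t in tables:
        up, down, _, _ = match_directional(reference, t)
        matched = up | down
        common = matched if common is None else common & matched
    return common or set()


def annotation_counts(annotations: AnnotationTable) -> dict[str, int]:
    """Number of '+' flags per functional category ('?' and '-' excluded)."""
    return {
        cat: sum(1 for flags in annotations.rows.values()
                 if flags[cat] == "+")
        for cat in AnnotationTable.CATEGORIES
    }


def venn_counts(a: RegulatorTable, b: RegulatorTable,
                ) -> dict[str, dict[str, int]]:
    """Two-set Venn region sizes per direction: a_only / shared / b_only."""
    out = {}
    for direction, sa, sb in (("up", set(a.up), set(b.up)),
                              ("down", set(a.down), set(b.down))):
        out[direction] = {
            "a_only": len(sa - sb),
            "shared": len(sa & sb),
            "b_only": len(sb - sa),
        }
    return out


def comparison_report(tables: dict[str, RegulatorTable],
                      reference_name: str) -> pd.DataFrame:
    """Direction-matched overlap of every table against the reference."""
    ref = tables[reference_name]
    rows = []
    for name, t in tables.items():
        if name == reference_name:
            continue
        up, down, n, total = match_directional(ref, t)
        rows.append({
            "treatment": name,
            "matched_up": len(up), "matched_down": len(down),
            "n_matched": n, "n_total": total,
            "matched_genes": ",".join(sorted(up | down)),
        })
    return pd.DataFrame(rows)
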