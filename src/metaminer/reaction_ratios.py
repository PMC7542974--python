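"""Variable expansion with reaction-pair ratios.

For every substrate -> product pair in a reaction-pair database whose two
compounds both map to measured variables, a new variable
``product_id/substrate_id`` is appended whose per-sample value is the
product intensity divided by the substrate intensity.  Such ratios track
the net activity of the reaction (and of its enzyme) better than either
intensity alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables_io import PeakTable

__all__ = ["ReactionPair", "ReactionPairDB", "load_reaction_db", "expand_ratios"]


@dataclass(frozen=True)
class ReactionPair:
    substrate_id: str
    product_id: str
    reaction_id: str
    enzyme: str | None = None
    reversible: bool = False


@dataclass
class ReactionPairDB:
    pairs: list[ReactionPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.pairs:
            if p.substrate_id == p.product_id:
                raise ValueError(
                    f"reaction {p.reaction_id}: substrate equals product "
                    f"({p.substrate_id})")
        triples = [(p.substrate_id, p.product_id, p.reaction_id) for p in self.pairs]
        seen, unique = set(), []
        dup = 0
        for pair, triple in zip(self.pairs, triples):
            if triple in seen:
                dup += 1
                continue
            seen.add(triple)
            unique.append(pair)
        if dup:
            warnings.warn(f"collapsed {dup} duplicate reaction pair(s)",
                          stacklevel=2)
        self.pairs = unique

    def __len__(self) -> int:
        return len(self.pairs)


def load_reaction_db(path) -> ReactionPairDB:
    """Read a tab-delimited reaction-pair table with columns substrate,
    product, reaction, enzyme, reversible."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"substrate", "product", "reaction"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"reaction DB lacks columns: {sorted(missing)}")
    pairs = []
    for i, row in frame.iterrows():
        if row["substrate"] == row["product"]:
            raise ValueError(
                f"row {i}: substrate equals product ({row['substrate']})")
        reversible = str(row.get("reversible", "")).strip().lower() in {
            "1", "true", "yes", "reversible"}
        enzyme = row.get("enzyme", "").strip() or None
        pairs.append(ReactionPair(row["substrate"], row["product"],
                                  row["reaction"], enzyme, reversible))
    return ReactionPairDB(pairs)


def expand_ratios(
    table: PeakTable,
    db: ReactionPairDB,
    annotation_map: Mapping[str, str],
    both_directions: bool = False,
) -> tuple[PeakTable, pd.DataFrame]:
    """Append product/substrate ratio variables to the table.

    ``annotation_map`` maps variable ids to compound ids.  When several
    variables map to one compound, the variable with the highest median
    intensity represents it (recorded in the provenance table).  A ratio is
    missing wherever the substrate intensity is zero or missing.  Reversible
    pairs contribute one ratio as listed unless ``both_directions`` is set.

    Returns the expanded table and a provenance table (one row per appended
    ratio: reaction, enzyme, the representing variables).
    """
    if not annotation_map:
        raise ValueError("annotation_map is empty")
    compound_to_var: dict[str, str] = {}
    for var, compound in annotation_map.items():
        if var not in table.data.columns:
            continue
        incumbent = compound_to_var.get(compound)
        if incumbent is None:
            compound_to_var[compound] = var
        else:
            med_new = table.data[var].median()
            med_old = table.data[incumbent].median()
            if pd.notna(med_new) and (pd.isna(med_old) or med_new > med_old):
                compound_to_var[compound] = var

    directed = []
    for p in db.pairs:
        directed.append((p.substrate_id, p.product_id, p))
        if both_directions and p.reversible:
            directed.append((p.product_id, p.substrate_id, p))

    new_cols: dict[str, pd.Series] = {}
    provenance_rows = []
    for substrate, product, pair in directed:
        sub_var = compound_to_var.get(substrate)
        prod_var = compound_to_var.get(product)
        if sub_var is None or prod_var is None:
            continue
        name = f"{product}/{substrate}"
        if name in new_cols or name in table.data.columns:
            continue
        denom = table.data[sub_var].where(table.data[sub_var] != 0)
        ratio = table.data[prod_var] / denom
        new_cols[name] = ratio.replace([np.inf, -np.inf], np.nan)
        provenance_rows.append({
            "ratio_variable": name, "reaction_id": pair.reaction_id,
            "enzyme": pair.enzyme, "substrate": substrate, "product": product,
            "substrate_variable": sub_var, "product_variable": prod_var,
            "reversible": pair.reversible})

    expanded = pd.concat([table.data, pd.DataFrame(new_cols, index=table.data.index)],
                         axis=1) if new_cols else table.data.copy()
    meta = table.variable_meta
    if meta is None:
        meta = pd.DataFrame(index=table.data.columns)
    meta = meta.reindex(expanded.columns)
    meta["is_ratio"] = [c in new_cols for c in expanded.columns]
    provenance = pd.DataFrame(provenance_rows, columns=[
        "ratio_variable", "reaction_id", "enzyme", "substrate", "product",
        "substrate_variable", "product_variable", "reversible"])
    if len(provenance):
        provenance = provenance.set_index("ratio_variable")
    return PeakTable(expanded, meta, table.log_transformed), provenance
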