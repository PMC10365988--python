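"""FFQ item -> LCA linkage: products, composition estimation, per-gram footprints.

An FFQ item is linked either *directly* to one LCA category (single-ingredient
foods and staples) or to a set of retail *products*, each an ordered ingredient
list.  UK labelling rules order ingredients by descending weight and only
sometimes declare percentages, so undeclared shares are estimated under two
constraints: the composition sums to 100% and each ingredient accounts for at
least as much of the product as the next one.  Items matched to several
products take the unweighted mean of the products' footprints; a
sold-to-consumed factor converts per-kg-as-sold values to per-gram-as-eaten.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import CompositionError, DataError, LinkageError
from .lca import INDICATORS, N_INDICATORS, IndicatorVector, LCADatabase

_TOL = 1e-9


@dataclass
class Ingredient:
    """One ingredient of a product, mapped to LCA categories.

    ``links`` is a list of ``(category_id, share)`` pairs whose shares sum to
    1; an ingredient that is itself a blend (e.g. "vegetable oil") can spread
    over several categories.  ``declared_percent`` is the manufacturer-stated
    percentage of the product, when printed on the label.
    """

    name: str
    links: list[tuple[str, float]]
    declared_percent: float | None = None
    organic: bool = False

    def __post_init__(self):
        if self.declared_percent is not None:
            p = float(self.declared_percent)
            if not (0.0 < p <= 100.0):
                raise DataError(f"ingredient {self.name!r}: declared percent must be in (0, 100], got {p}")
            self.declared_percent = p
        if not self.links:
            raise DataError(f"ingredient {self.name!r} has no category links")
        shares = np.array([s for _, s in self.links], dtype=float)
        if (shares < 0).any() or abs(shares.sum() - 1.0) > _TOL:
            raise DataError(f"ingredient {self.name!r}: link shares must be >= 0 and sum to 1")


@dataclass
class Product:
    """A retail product: ordered ingredient list (label order = descending weight)."""

    id: str
    ingredients: list[Ingredient]
    resolved_percents: np.ndarray | None = None

    def declared(self) -> list[float | None]:
        return [ing.declared_percent for ing in self.ingredients]


@dataclass
class FFQItem:
    """One food-frequency-questionnaire item and how it resolves to LCA data.

    Exactly one of ``category`` (direct link) or ``products`` (keyword-matched
    product ids) is populated.  ``conversion_factor`` converts mass as sold to
    mass as consumed (cooking gains/losses, inedible fractions); ``is_meat``
    marks items whose intake counts toward the meat-eater cut-offs.
    """

    id: str
    name: str = ""
    category: str | None = None
    products: list[str] = field(default_factory=list)
    conversion_factor: float = 1.0
    is_meat: bool = False

    def __post_init__(self):
        if (self.category is None) == (not self.products):
            raise DataError(f"FFQ item {self.id!r}: exactly one of category/products must be set")
        if not self.conversion_factor > 0:
            raise DataError(f"FFQ item {self.id!r}: conversion factor must be > 0")

    @property
    def kind(self) -> str:
        return "direct" if self.category is not None else "products"


def estimate_composition(product: Product | list[float | None]) -> np.ndarray:
    """Resolve a product's percent composition under the labelling constraints.

    Declared percentages are honoured exactly; the residual mass is spread as
    equally as the ordering permits over the undeclared ingredients, with the
    declared values acting as ceilings/floors on the runs between them (the
    exact limit of equal splitting followed by pooling adjacent violators
    around fixed anchors).  Deterministic; raises :class:`CompositionError`
    with a diagnosis when the declarations are infeasible.
    """
    declared = product.declared() if isinstance(product, Product) else list(product)
    n = len(declared)
    if n == 0:
        raise CompositionError("product has no ingredients")
    values = np.zeros(n)
    fixed = np.zeros(n, dtype=bool)
    last = None
    total = 0.0
    for i, d in enumerate(declared):
        if d is None:
            continue
        d = float(d)
        if not (0.0 < d <= 100.0):
            raise CompositionError(f"declared percent at position {i} out of (0, 100]: {d}")
        if last is not None and d > last + _TOL:
            raise CompositionError(
                f"declared percent at position {i} ({d}) exceeds an earlier declared value ({last})"
            )
        values[i] = d
        fixed[i] = True
        last = d
        total += d
    if total > 100.0 + 1e-6:
        raise CompositionError(f"declared percents sum to {total}, which exceeds 100")

    free = np.flatnonzero(~fixed)
    if free.size == 0:
        if abs(total - 100.0) > 1e-6:
            raise CompositionError(f"fully declared product sums to {total}, not 100")
        return values
    residual = 100.0 - total

    # Maximal runs of undeclared ingredients between declared anchors.  Within
    # a run the mass-minimising allocation is a common value bounded by the
    # surrounding anchors (ceiling = previous declared value, floor = next);
    # spreading the residual as equally as the ordering allows is equivalent
    # to clipping one common level `lam` into every run's bounds and solving
    # the (monotone) mass balance for `lam`.
    runs = []  # (indices, ceiling, floor)
    i = 0
    while i < n:
        if fixed[i]:
            i += 1
            continue
        j = i
        while j < n and not fixed[j]:
            j += 1
        ceiling = values[i - 1] if i > 0 else np.inf
        floor = values[j] if j < n else 0.0
        runs.append((np.arange(i, j), ceiling, floor))
        i = j

    lo_sum = sum(len(idx) * floor for idx, _, floor in runs)
    hi_sum = sum(len(idx) * ceil for idx, ceil, _ in runs)
    if residual < lo_sum - 1e-6:
        raise CompositionError(
            "declared percents are infeasible: later declared values require at least "
            f"{lo_sum:.4f}% of undeclared mass but only {residual:.4f}% remains"
        )
    if residual > hi_sum + 1e-6:
        raise CompositionError(
            "declared percents are infeasible: undeclared ingredients can absorb at most "
            f"{hi_sum:.4f}% but {residual:.4f}% remains"
        )

    def mass(lam):
        return sum(len(idx) * min(max(lam, floor), ceil) for idx, ceil, floor in runs)

    lam_lo, lam_hi = 0.0, max([residual, 100.0] + [c for _, c, _ in runs if np.isfinite(c)])
    for _ in range(100):
        mid = 0.5 * (lam_lo + lam_hi)
        if mass(mid) < residual:
            lam_lo = mid
        else:
            lam_hi = mid
    lam = 0.5 * (lam_lo + lam_hi)
    for idx, ceil, floor in runs:
        values[idx] = min(max(lam, floor), ceil)

    if abs(values.sum() - 100.0) > 1e-6 or (np.diff(values) > 1e-6).any() or (values < -_TOL).any():
        raise CompositionError("composition constraints could not be satisfied")
    return np.maximum(values, 0.0)


def resolve_product(product: Product) -> Product:
    """Return the product with ``resolved_percents`` filled in."""
    if product.resolved_percents is None:
        product.resolved_percents = estimate_composition(product)
    return product


def product_footprint_per_kg(product: Product, lookup) -> np.ndarray:
    """Per-kg indicator vector of a product.

    ``lookup(category_id, organic)`` must return a length-7 per-kg indicator
    array (a category median or a random draw).  The product's footprint is
    the composition-weighted sum over ingredients of their link-share-weighted
    category vectors; organic ingredients use the organic record variant.
    """
    resolve_product(product)
    out = np.zeros(N_INDICATORS)
    for ing, pct in zip(product.ingredients, product.resolved_percents):
        if pct == 0.0:
            continue
        vec = np.zeros(N_INDICATORS)
        for cat, share in ing.links:
            if share:
                vec += share * np.asarray(lookup(cat, ing.organic), dtype=float)
        out += (pct / 100.0) * vec
    return out


def ffq_item_footprint_per_g(item: FFQItem, lookup, products: dict[str, Product] | None = None) -> np.ndarray:
    """Per-gram-as-consumed indicator vector of an FFQ item.

    Direct items take their category's vector; product-matched items take the
    unweighted arithmetic mean over matched products.  The per-kg result is
    divided by 1000 and multiplied by the item's sold-to-consumed conversion
    factor so it applies to grams as eaten.
    """
    if item.category is not None:
        per_kg = np.asarray(lookup(item.category, False), dtype=float)
    else:
        if products is None:
            raise LinkageError(f"item {item.id!r} links to products but no product catalog was given")
        matched = []
        for pid in item.products:
            if pid not in products:
                raise LinkageError(f"item {item.id!r}: product {pid!r} not in catalog")
            matched.append(product_footprint_per_kg(products[pid], lookup))
        if not matched:
            raise LinkageError(f"item {item.id!r} has an empty product match set")
        per_kg = np.mean(matched, axis=0)
    return per_kg / 1000.0 * item.conversion_factor


class LinkTable:
    """The FFQ-item link table plus the product catalog it references."""

    def __init__(self, items: list[FFQItem], products: list[Product] | None = None):
        self.items: dict[str, FFQItem] = {}
        for it in items:
            if it.id in self.items:
                raise DataError(f"duplicate FFQ item id {it.id!r}")
            self.items[it.id] = it
        self.products: dict[str, Product] = {}
        for p in products or []:
            if p.id in self.products:
                raise DataError(f"duplicate product id {p.id!r}")
            self.products[p.id] = p
        for it in self.items.values():
            for pid in it.products:
                if pid not in self.products:
                    raise LinkageError(f"item {it.id!r} references unknown product {pid!r}")

    @property
    def item_ids(self) -> list[str]:
        return list(self.items)

    @property
    def meat_item_ids(self) -> list[str]:
        return [i for i, it in self.items.items() if it.is_meat]

    def item_footprint_per_g(self, item_id: str, lookup) -> np.ndarray:
        return ffq_item_footprint_per_g(self.items[item_id], lookup, self.products)

    def median_footprints_per_g(self, db: LCADatabase) -> dict[str, np.ndarray]:
        """Per-gram vectors with every category fixed at its database median."""
        lookup = lambda cat, organic: db.category_median(cat, organic=True if organic else None)
        return {i: self.item_footprint_per_g(i, lookup) for i in self.items}

    # -- JSON interchange --------------------------------------------------

    def to_json(self, path=None):
        doc = {
            "items": [
                {
                    "id": it.id,
                    "name": it.name,
                    "kind": it.kind,
                    "category": it.category,
                    "products": it.products,
                    "conversion_factor": it.conversion_factor,
                    "is_meat": it.is_meat,
                }
                for it in self.items.values()
            ],
            "products": [
                {
                    "id": p.id,
                    "ingredients": [
                        {
                            "name": ing.name,
                            "declared_percent": ing.declared_percent,
                            "links": [[c, s] for c, s in ing.links],
                            "organic": ing.organic,
                        }
                        for ing in p.ingredients
                    ],
                }
                for p in self.products.values()
            ],
        }
        if path is None:
            return json.dumps(doc, indent=1)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
        return None

    @classmethod
    def from_json(cls, path_or_str) -> "LinkTable":
        if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("{"):
            doc = json.loads(path_or_str)
        else:
            with open(path_or_str) as fh:
                doc = json.load(fh)
        items = [
            FFQItem(
                id=d["id"],
                name=d.get("name", ""),
                category=d.get("category"),
                products=d.get("products") or [],
                conversion_factor=d.get("conversion_factor", 1.0),
                is_meat=d.get("is_meat", False),
            )
            for d in doc["items"]
        ]
        products = [
            Product(
                id=d["id"],
                ingredients=[
                    Ingredient(
                        name=i["name"],
                        declared_percent=i.get("declared_percent"),
                        links=[(c, float(s)) for c, s in i["links"]],
                        organic=i.get("organic", False),
                    )
                    for i in d["ingredients"]
                ],
            )
            for d in doc.get("products", [])
        ]
        return cls(items, products)
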