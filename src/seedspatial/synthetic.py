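"""Synthetic Stereo-seq-like wheat seed sections with known ground truth.

A 14 DPA wheat seed cut through its lateral sides shows tissue zones in
concentric layers: pericarp outermost, then the sub-aleurone ring of the
endosperm, central endosperm, inner endosperm, the transfer cells, and
the outer and inner crease at the centre, with the embryo as a distinct
disc embedded in the endosperm.  This module emulates such a section on
an abstract DNB grid:

* geometry: concentric elliptical annuli (:func:`make_default_template`),
  the embryo as an offset disc overriding the endosperm bands;
* expression: each zone has a Poisson expression program (housekeeping
  baseline, zone markers elevated by a configurable fold, homeolog triads
  with planted A:B:D bias ratios) plus low background noise outside the
  tissue;
* capture: every transcript count is Poisson with rate
  ``zone_rate x capture_rate``; DNBs capturing nothing are absent from
  the emitted GEM table, as on a real sparse capture array.

Ground truth (per-DNB zone map, per-bin majority zones, planted markers
and bias ratios) is emitted alongside so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, SizingError

#: canonical zone order, outermost to innermost, plus the embryo disc
ZONE_NAMES = (
    "pericarp",
    "sub-aleurone",
    "central endosperm",
    "inner endosperm",
    "transfer cells",
    "outer crease",
    "inner crease",
    "embryo",
)

BACKGROUND = "background"
ARTIFACT = "fold_artifact"

# radial band boundaries (fractions of the outer ellipse), innermost first.
# Chosen so every band is about two Bin50 bins across at the default scale,
# which keeps the fraction of boundary-straddling bins manageable.
_BAND_EDGES = (0.0, 0.22, 0.37, 0.51, 0.64, 0.77, 0.89, 1.0)


@dataclass(frozen=True)
class ZoneSpec:
    """One concentric band (or the embryo disc) of the tissue template."""

    zone_id: str
    r_inner: float          # radial fraction, inclusive
    r_outer: float          # radial fraction, exclusive
    is_disc: bool = False   # embryo: disc centred at (cx, cy) below
    cx: float = 0.0
    cy: float = 0.0
    ax: float = 0.0         # disc semi-axes in DNB units
    ay: float = 0.0


@dataclass(frozen=True)
class ZoneTemplate:
    """Elliptical-annulus tissue template on a DNB grid."""

    section_width: int
    section_height: int
    center: tuple[float, float]
    semi_axes: tuple[float, float]      # outer ellipse (a, b), DNB units
    zones: tuple[ZoneSpec, ...]         # ordered outermost -> innermost, embryo last
    artifact: ZoneSpec | None = None    # optional duplicated-tissue patch
    quantize: int = 1                   # zone boundaries follow a q x q lattice

    def _cell_center(self, x, y):
        q = self.quantize
        if q <= 1:
            return x, y
        return (np.floor_divide(x, q) + 0.5) * q, (np.floor_divide(y, q) + 0.5) * q

    def radial_fraction(self, x, y):
        a, b = self.semi_axes
        cx, cy = self.center
        xq, yq = self._cell_center(np.asarray(x), np.asarray(y))
        return np.sqrt(((xq - cx) / a) ** 2 + ((yq - cy) / b) ** 2)

    def in_disc(self, x, y, z: "ZoneSpec"):
        xq, yq = self._cell_center(np.asarray(x), np.asarray(y))
        return ((xq - z.cx) / z.ax) ** 2 + ((yq - z.cy) / z.ay) ** 2 < 1.0


def make_default_template(scale: int = 1500, artifact: bool = False,
                          quantize: int = 50) -> ZoneTemplate:
    """Eight-zone concentric template on a ``scale`` x ``scale`` DNB grid.

    Bands from outermost to innermost: pericarp, sub-aleurone, central
    endosperm, inner endosperm, transfer cells, outer crease, inner
    crease; the embryo is a disc offset toward one end of the section,
    overriding the endosperm bands it overlaps.

    Zone boundaries are quantized to a ``quantize`` x ``quantize`` DNB
    lattice (membership is decided at the lattice-cell centre), so the
    planted zones are resolvable at the analysis bin size instead of
    being dominated by partial-bin mixing; pass ``quantize=1`` for
    smooth elliptical boundaries.
    """
    if scale < 500:
        raise SizingError(
            f"scale={scale} too small: bands need >= 2 Bin50 bins each; "
            "use scale >= 500")
    cx = cy = scale / 2.0
    a, b = 0.49 * scale, 0.46 * scale
    band_zones = []
    # ZONE_NAMES[:7] is outermost->innermost; edges are innermost-first
    for name, r_in, r_out in zip(
            reversed(ZONE_NAMES[:7]), _BAND_EDGES[:-1], _BAND_EDGES[1:]):
        band_zones.append(ZoneSpec(zone_id=name, r_inner=r_in, r_outer=r_out))
    band_zones = band_zones[::-1]  # store outermost first, matching ZONE_NAMES
    embryo = ZoneSpec(
        zone_id="embryo", r_inner=0.0, r_outer=0.0, is_disc=True,
        cx=cx + 0.62 * a, cy=cy, ax=0.16 * a, ay=0.16 * b)
    art = None
    if artifact:
        # duplicated-tissue patch outside the section, used to exercise
        # the cluster-discard logic
        art = ZoneSpec(
            zone_id=ARTIFACT, r_inner=0.0, r_outer=0.0, is_disc=True,
            cx=0.12 * scale, cy=0.12 * scale,
            ax=0.105 * scale, ay=0.105 * scale)
    return ZoneTemplate(
        section_width=scale, section_height=scale, center=(cx, cy),
        semi_axes=(a, b), zones=tuple(band_zones) + (embryo,), artifact=art,
        quantize=quantize)


def assign_zone(x, y, template: ZoneTemplate) -> str | None:
    """Zone id at DNB coordinate (x, y), or ``None`` for background.

    Deterministic partition: the embryo disc wins where it overlaps the
    bands; annuli are half-open, inner-inclusive ``[r_in, r_out)``.
    """
    if not (0 <= x < template.section_width and 0 <= y < template.section_height):
        raise DomainError(f"coordinate ({x}, {y}) outside section bounds")
    r = float(template.radial_fraction(x, y))

    if (template.artifact is not None and r >= 1.0
            and template.in_disc(x, y, template.artifact)):
        return ARTIFACT
    if r >= 1.0:
        return None
    for z in template.zones:
        if z.is_disc and template.in_disc(x, y, z):
            return z.zone_id
    for z in template.zones:
        if not z.is_disc and z.r_inner <= r < z.r_outer:
            return z.zone_id
    return None


def zone_code_names(template: ZoneTemplate) -> list[str]:
    """Integer-code -> zone-name table used by :func:`zone_map` (code 0 = background)."""
    names = [BACKGROUND] + [z.zone_id for z in template.zones]
    if template.artifact is not None:
        names.append(template.artifact.zone_id)
    return names


def zone_map(template: ZoneTemplate) -> np.ndarray:
    """(height x width) int8 array of zone codes (0 = background).

    Cached per template; treat the returned array as read-only.
    """
    cached = _ZONE_MAP_CACHE.get(template)
    if cached is not None:
        return cached
    h, w = template.section_height, template.section_width
    yy, xx = np.mgrid[0:h, 0:w]
    r = template.radial_fraction(xx, yy)
    codes = np.zeros((h, w), dtype=np.int8)
    names = zone_code_names(template)
    for z in template.zones:
        if z.is_disc:
            inside = template.in_disc(xx, yy, z)
            inside &= r < 1.0  # disc only counts inside the tissue
        else:
            inside = (r >= z.r_inner) & (r < z.r_outer)
        codes[inside] = names.index(z.zone_id)
    if template.artifact is not None:
        z = template.artifact
        inside = template.in_disc(xx, yy, z)
        inside &= r >= 1.0  # patch sits outside the real tissue
        codes[inside] = names.index(z.zone_id)
    if len(_ZONE_MAP_CACHE) > 8:
        _ZONE_MAP_CACHE.clear()
    _ZONE_MAP_CACHE[template] = codes
    return codes


_ZONE_MAP_CACHE: dict = {}


@dataclass(frozen=True)
class HomeologTriad:
    """A/B/D homeolog ids for one gene family; absent copies are ``None``."""

    family: str
    gene_a: str | None
    gene_b: str | None
    gene_d: str | None

    def present(self) -> dict[str, str]:
        out = {}
        for sub, g in (("A", self.gene_a), ("B", self.gene_b), ("D", self.gene_d)):
            if g is not None:
                out[sub] = g
        return out


@dataclass
class GeneModel:
    """Per-zone Poisson expression programs over a fixed gene list.

    ``rates`` maps zone_id -> {gene_id -> mean transcripts per DNB}
    before capture thinning.  ``background_rates`` applies outside the
    tissue mask.  ``side_asymmetry`` multiplies all rates on the
    ``y >= section_height/2`` half, mimicking the brighter side of a
    real seed section; the default 1.0 disables it.
    """

    gene_ids: list[str]
    rates: dict[str, dict[str, float]]
    background_rates: dict[str, float]
    markers: dict[str, list[str]]               # zone -> planted marker genes
    triads: list[HomeologTriad] = field(default_factory=list)
    triad_bias: dict[str, dict[str, float]] = field(default_factory=dict)
    side_asymmetry: float = 1.0

    def rate_vector(self, zone_id: str) -> np.ndarray:
        table = self.background_rates if zone_id in (BACKGROUND,) else self.rates[zone_id]
        return np.array([table.get(g, 0.0) for g in self.gene_ids])

    def validate(self) -> None:
        for zone, table in self.rates.items():
            for g, r in table.items():
                if not np.isfinite(r) or r < 0:
                    raise ParameterError(f"rate for {g} in {zone} must be finite >= 0")
        for fam, ratios in self.triad_bias.items():
            if any(v <= 0 for v in ratios.values()):
                raise ParameterError(
                    f"triad {fam}: bias ratios must be strictly positive "
                    "(encode an absent homeolog as missing, not rate 0)")


# Planted triads.  Bias magnitudes follow the overall MID totals observed
# for three wheat families: puroindoline-B (D >> B > A), a metallothionein
# isoform with no A homeolog in the reference genome (D >> B), and
# alpha-amylase/subtilisin inhibitor (A << B, D).
_TRIAD_SPECS = [
    # family, (A, B, D) relative expression, zones where expressed
    ("puroindolineB", (2836.0, 7387.0, 24634.0),
     ("sub-aleurone", "central endosperm", "inner endosperm")),
    ("metallothionein", (None, 2131.0, 21397.0),
     ("embryo", "pericarp", "outer crease", "inner crease")),
    ("aasi", (123.0, 4286.0, 2730.0), ("pericarp",)),
]


def default_gene_model(
    n_housekeeping: int = 40,
    housekeeping_rate: float = 0.05,
    markers_per_zone: int = 5,
    marker_rate: float = 0.7,
    marker_fold: float = 10.0,
    background_total_rate: float = 0.05,
    triad_scale: float = 0.36,
    side_asymmetry: float = 1.0,
) -> GeneModel:
    """Default gene model for the eight-zone template.

    Every zone expresses all housekeeping genes at a common baseline and
    carries ``markers_per_zone`` planted markers whose in-zone rate
    exceeds their rate everywhere else by ``marker_fold``.  Triads are
    planted with the bias ratios described in :data:`_TRIAD_SPECS`,
    scaled so the strongest homeolog has rate ``triad_scale``.
    """
    if marker_fold <= 1:
        raise ParameterError("marker_fold must exceed 1")
    hk = [f"HK{i:03d}" for i in range(n_housekeeping)]
    markers: dict[str, list[str]] = {}
    marker_genes: list[str] = []
    for zone in ZONE_NAMES:
        tag = zone.replace(" ", "_").replace("-", "_")
        ms = [f"MK_{tag}_{j}" for j in range(markers_per_zone)]
        markers[zone] = ms
        marker_genes.extend(ms)

    triads, triad_bias, triad_genes = [], {}, []
    triad_rates: dict[str, dict[str, float]] = {}
    for fam, (ra, rb, rd), zones in _TRIAD_SPECS:
        ids = {}
        for sub, rel in (("A", ra), ("B", rb), ("D", rd)):
            if rel is not None:
                ids[sub] = f"TRIAD_{fam}_{sub}"
        triads.append(HomeologTriad(fam, ids.get("A"), ids.get("B"), ids.get("D")))
        rels = {s: r for s, r in (("A", ra), ("B", rb), ("D", rd)) if r is not None}
        top = max(rels.values())
        triad_bias[fam] = {s: r / min(rels.values()) for s, r in rels.items()}
        for sub, rel in rels.items():
            g = ids[sub]
            triad_genes.append(g)
            for zone in zones:
                triad_rates.setdefault(zone, {})[g] = triad_scale * rel / top

    gene_ids = hk + marker_genes + triad_genes
    rates: dict[str, dict[str, float]] = {}
    for zone in ZONE_NAMES:
        table = {g: housekeeping_rate for g in hk}
        for other_zone, ms in markers.items():
            r = marker_rate if other_zone == zone else marker_rate / marker_fold
            for g in ms:
                table[g] = r
        for g, r in triad_rates.get(zone, {}).items():
            table[g] = r
        rates[zone] = table
    # the fold artifact is a doubled-over flap of central endosperm:
    # same program at twice the capture density (two tissue layers)
    rates[ARTIFACT] = {g: 2.0 * r for g, r in rates["central endosperm"].items()}

    bg_per_gene = background_total_rate / n_housekeeping
    background = {g: bg_per_gene for g in hk}
    model = GeneModel(
        gene_ids=gene_ids, rates=rates, background_rates=background,
        markers=markers, triads=triads, triad_bias=triad_bias,
        side_asymmetry=side_asymmetry)
    model.validate()
    return model


DEFAULT_CAPTURE_RATE = 0.085


@dataclass
class GroundTruth:
    """Planted truth emitted with every simulated section."""

    zone_codes: np.ndarray              # (h, w) int8, 0 = background
    code_names: list[str]
    markers: dict[str, list[str]]
    triad_bias: dict[str, dict[str, float]]
    seed: int

    def zone_of(self, x: int, y: int) -> str:
        return self.code_names[self.zone_codes[y, x]]

    def bin_majority_zones(self, bin_size: int) -> pd.DataFrame:
        """Majority zone per bin (background included in the vote)."""
        h, w = self.zone_codes.shape
        nbx, nby = -(-w // bin_size), -(-h // bin_size)
        n_codes = len(self.code_names)
        yy, xx = np.mgrid[0:h, 0:w]
        key = (xx // bin_size) * nby + (yy // bin_size)
        hist = np.zeros(((nbx * nby), n_codes), dtype=np.int64)
        np.add.at(hist, (key.ravel(), self.zone_codes.ravel()), 1)
        maj = hist.argmax(axis=1)
        bx, by = np.divmod(np.arange(nbx * nby), nby)
        return pd.DataFrame({
            "bin_x": bx, "bin_y": by,
            "zone": [self.code_names[c] for c in maj],
        })

    def tissue_bins(self, bin_size: int) -> set[tuple[int, int]]:
        """Bins whose majority zone is real tissue (not background/artifact)."""
        tab = self.bin_majority_zones(bin_size)
        keep = ~tab["zone"].isin([BACKGROUND, ARTIFACT])
        return set(zip(tab.loc[keep, "bin_x"], tab.loc[keep, "bin_y"]))

    def write_tsv(self, path) -> None:
        h, w = self.zone_codes.shape
        ys, xs = np.nonzero(self.zone_codes)
        pd.DataFrame({
            "x": xs, "y": ys,
            "zone_id": [self.code_names[c] for c in self.zone_codes[ys, xs]],
        }).sort_values(["x", "y"]).to_csv(path, sep="\t", index=False)


def simulate_section(
    template: ZoneTemplate,
    model: GeneModel,
    capture_rate: float = DEFAULT_CAPTURE_RATE,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one capture chip: a GEM table plus its ground truth.

    Per DNB and gene, the captured MID count is Poisson with rate
    ``zone_rate x capture_rate`` (times ``side_asymmetry`` on the boosted
    half).  DNBs with total count 0 do not appear in the GEM table.
    Identical inputs give byte-identical output.
    """
    if not (0 < capture_rate <= 1):
        raise ParameterError(f"capture_rate must be in (0, 1], got {capture_rate}")
    model.validate()
    rng = np.random.default_rng(seed)
    codes = zone_map(template)
    names = zone_code_names(template)
    h, w = codes.shape
    half_mask = (np.arange(h)[:, None] >= h / 2) & np.ones((h, w), bool)

    rec_gene, rec_pix, rec_cnt = [], [], []
    flat_codes = codes.ravel()
    flat_half = half_mask.ravel()
    gene_arr = np.array(model.gene_ids)
    for code, zone_name in enumerate(names):
        zone_pix_all = np.flatnonzero(flat_codes == code)
        if len(zone_pix_all) == 0:
            continue
        base = model.rate_vector(zone_name) * capture_rate
        if not base.any():
            continue
        for boosted in (False, True):
            pix = zone_pix_all[flat_half[zone_pix_all] == boosted]
            if len(pix) == 0:
                continue
            lam = base * (model.side_asymmetry if boosted else 1.0)
            totals = rng.poisson(lam * len(pix))
            for gi in np.flatnonzero(totals):
                placed = rng.integers(0, len(pix), totals[gi])
                cnt = np.bincount(placed, minlength=len(pix))
                nz = np.flatnonzero(cnt)
                rec_gene.append(np.full(len(nz), gi))
                rec_pix.append(pix[nz])
                rec_cnt.append(cnt[nz])

    if rec_gene:
        gi = np.concatenate(rec_gene)
        pix = np.concatenate(rec_pix)
        cnt = np.concatenate(rec_cnt)
        gem = pd.DataFrame({
            "geneID": gene_arr[gi],
            "x": (pix % w).astype(np.int64),
            "y": (pix // w).astype(np.int64),
            "MIDCount": cnt.astype(np.int64),
        })
        gem = gem.sort_values(["geneID", "x", "y"], kind="mergesort").reset_index(drop=True)
    else:
        gem = pd.DataFrame({"geneID": pd.Series([], dtype=str),
                            "x": pd.Series([], dtype=np.int64),
                            "y": pd.Series([], dtype=np.int64),
                            "MIDCount": pd.Series([], dtype=np.int64)})
    truth = GroundTruth(zone_codes=codes, code_names=names,
                        markers=model.markers, triad_bias=model.triad_bias,
                        seed=seed)
    return gem, truth


def expected_mids_per_captured_dnb(template: ZoneTemplate, model: GeneModel,
                                   capture_rate: float) -> float:
    """Analytic mean MIDs per capturing in-tissue DNB for a capture rate.

    With per-DNB total rate L the expectation is L / (1 - exp(-L)),
    averaged over the tissue zones weighted by their pixel counts.
    """
    codes = zone_map(template)
    names = zone_code_names(template)
    num = den = 0.0
    for code, zone in enumerate(names):
        if zone in (BACKGROUND, ARTIFACT):
            continue
        n_pix = int((codes == code).sum())
        if n_pix == 0:
            continue
        lam = model.rate_vector(zone).sum() * capture_rate
        num += n_pix * lam
        den += n_pix * (1.0 - np.exp(-lam))
    return num / den


def calibrate_capture_rate(template: ZoneTemplate, model: GeneModel,
                           target: float = 1.3, tol: float = 1e-3) -> float:
    """Bisection on capture_rate so the expected MIDs per capturing DNB
    matches ``target`` (1.3 emulates the focus chip)."""
    lo, hi = 1e-6, 1.0
    f = lambda c: expected_mids_per_captured_dnb(template, model, c) - target
    if f(hi) < 0:
        raise ParameterError("target MIDs/DNB unreachable at capture_rate <= 1")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if abs(f(mid)) < tol:
            return mid
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
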