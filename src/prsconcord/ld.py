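"""SNP overlap between two scores, counting LD proxies.

A variant of score A is *represented* in score B if the same variant appears
in B (matched by id, falling back to chromosome:position), or if some B
variant on the same chromosome within a search window is in linkage
disequilibrium with it at R^2 above a threshold.  R^2 is the squared Pearson
correlation of the two dosage vectors in the analysis panel (the composite
LD estimator for unphased dosages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import DosagePanel, ScoreFile


@dataclass
class LdOverlapResult:
    n_direct: int
    n_proxy: int
    n_unmatched: int
    overlap_fraction: float
    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    r2_threshold: float = 0.8

    def check(self, n_snps_a: int) -> None:
        if self.n_direct + self.n_proxy + self.n_unmatched != n_snps_a:
            raise ValidationError("overlap counts do not sum to the score-A variant count")

    def summary(self) -> str:
        return (
            f"n_direct\t{self.n_direct}\nn_proxy\t{self.n_proxy}\n"
            f"n_unmatched\t{self.n_unmatched}\noverlap_fraction\t{self.overlap_fraction:.4f}"
        )


def dosage_r2(panel: DosagePanel, variant_x, variant_y) -> float:
    """Squared Pearson correlation of two variants' dosage vectors."""
    ix = variant_x if isinstance(variant_x, (int, np.integer)) else panel.index_of(str(variant_x))
    iy = variant_y if isinstance(variant_y, (int, np.integer)) else panel.index_of(str(variant_y))
    if ix is None or iy is None:
        raise ValidationError("variant not present in panel")
    x = panel.dosages[ix]
    y = panel.dosages[iy]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValidationError("monomorphic variant: LD undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def overlap(
    score_a: ScoreFile,
    score_b: ScoreFile,
    panel: DosagePanel,
    r2_threshold: float = 0.8,
    window: int = 500_000,
) -> LdOverlapResult:
    """Count score-A variants represented in score B directly or via LD proxy.

    Direct matches are keyed by variant id with a chromosome:position
    fallback.  For the rest, the best-R^2 B variant on the same chromosome
    within ``±window`` bp is a proxy when R^2 is strictly above the
    threshold; ties on R^2 break by smaller base-pair distance, then
    lexicographic variant id.  Variants absent from the panel (either side)
    cannot be proxied and count as unmatched.
    """
    b_ids = set(score_b.variant_ids)
    b_pos = {(v.chromosome, v.position) for v in score_b.variants}
    b_in_panel = []
    for v in score_b.variants:
        i = panel.index_of(v.variant_id, v.chromosome, v.position)
        if i is not None:
            b_in_panel.append((v, i))

    n_direct = n_proxy = n_unmatched = 0
    pairs: list[tuple[str, str, float]] = []
    for va in score_a.variants:
        if va.variant_id in b_ids or (va.chromosome, va.position) in b_pos:
            n_direct += 1
            pairs.append((va.variant_id, va.variant_id, 1.0))
            continue
        ia = panel.index_of(va.variant_id, va.chromosome, va.position)
        if ia is None:
            n_unmatched += 1
            continue
        xa = panel.dosages[ia]
        sa = xa.std()
        if sa == 0:
            n_unmatched += 1
            continue
        best = None  # (-r2, distance, id, r2)
        for vb, ib in b_in_panel:
            if vb.chromosome != va.chromosome or abs(vb.position - va.position) > window:
                continue
            xb = panel.dosages[ib]
            if xb.std() == 0:
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            r2 = r * r
            key = (-r2, abs(vb.position - va.position), vb.variant_id)
            if best is None or key < best[0]:
                best = (key, vb.variant_id, r2)
        if best is not None and best[2] > r2_threshold:
            n_proxy += 1
            pairs.append((va.variant_id, best[1], best[2]))
        else:
            n_unmatched += 1

    result = LdOverlapResult(
        n_direct=n_direct,
        n_proxy=n_proxy,
        n_unmatched=n_unmatched,
        overlap_fraction=(n_direct + n_proxy) / len(score_a) if len(score_a) else 0.0,
        pairs=pairs,
        r2_threshold=r2_threshold,
    )
    result.check(len(score_a))
    return result
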