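"""Lineage-level virus-host dynamics.

Given population abundance matrices, population-level virus-host links and
a host-population -> phylum map, this module computes per-lineage
virus-host abundance ratios (VHRs), abundance correlations, host and viral
ranges, and lifestyle (virulent vs temperate) abundance trends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from amdvir.abundance import AbundanceMatrix
from amdvir.records import VirusHostLink

logger = logging.getLogger(__name__)


@dataclass
class LineageSummary:
    phylum: str
    n_host_populations: int
    n_virus_populations: int
    vhr_per_sample: pd.Series
    mean_log10_vhr: float
    abundance_correlation: tuple[float, float] | None  # (r, p) or None
    host_range_mean: float | None = None
    viral_range_mean: float | None = None
    virulent_temperate_ratio: float | None = None


def _phylum_groups(
    links: Sequence[VirusHostLink], phylum_map: Mapping[str, str]
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Hosts per phylum (from the map) and viruses linked to each phylum."""
    hosts: dict[str, set[str]] = {}
    viruses: dict[str, set[str]] = {}
    for host, phylum in phylum_map.items():
        hosts.setdefault(phylum, set()).add(host)
    for l in links:
        phylum = phylum_map.get(l.host_population)
        if phylum is None:
            continue
        viruses.setdefault(phylum, set()).add(l.virus_population)
    return hosts, viruses


def lineage_vhr(
    virus_abund: AbundanceMatrix,
    host_abund: AbundanceMatrix,
    links: Sequence[VirusHostLink],
    phylum_map: Mapping[str, str],
    split_shared: bool = False,
) -> dict[str, pd.Series]:
    """Per-sample virus-host abundance ratio (VHR) for each host phylum.

    VHR(sample, phylum) = sum of abundances of viruses linked to the phylum
    divided by the summed abundance of the phylum's host populations;
    samples where either sum is zero are excluded. Viruses linked to
    several phyla contribute their full abundance to each by default;
    ``split_shared`` divides it equally instead.
    """
    v = virus_abund.to_frame()
    h = host_abund.to_frame()
    hosts, viruses = _phylum_groups(links, phylum_map)
    n_phyla_per_virus: dict[str, int] = {}
    for phylum, vs in viruses.items():
        for vid in vs:
            n_phyla_per_virus[vid] = n_phyla_per_virus.get(vid, 0) + 1
    out: dict[str, pd.Series] = {}
    for phylum in sorted(hosts):
        vs = sorted(viruses.get(phylum, ()))
        if not vs:
            logger.warning("phylum %s has no linked viruses; omitted", phylum)
            continue
        weights = (
            np.array([1.0 / n_phyla_per_virus[vid] for vid in vs])
            if split_shared
            else np.ones(len(vs))
        )
        vsum = v.reindex(vs).fillna(0.0).mul(weights, axis=0).sum(axis=0)
        hsum = h.reindex(sorted(hosts[phylum])).fillna(0.0).sum(axis=0)
        keep = (vsum > 0) & (hsum > 0)
        out[phylum] = (vsum[keep] / hsum[keep]).rename(phylum)
    return out


def lineage_abundance_correlation(
    virus_abund: AbundanceMatrix,
    host_abund: AbundanceMatrix,
    links: Sequence[VirusHostLink],
    phylum_map: Mapping[str, str],
) -> dict[str, tuple[float, float] | None]:
    """Pearson correlation (r, two-tailed p) between summed host abundance
    and summed linked-virus abundance per phylum, across samples where both
    are detected (> 0). Fewer than 3 co-detected samples, or zero variance,
    yields ``None``."""
    v = virus_abund.to_frame()
    h = host_abund.to_frame()
    hosts, viruses = _phylum_groups(links, phylum_map)
    out: dict[str, tuple[float, float] | None] = {}
    for phylum in sorted(hosts):
        vs = sorted(viruses.get(phylum, ()))
        if not vs:
            continue
        vsum = v.reindex(vs).fillna(0.0).sum(axis=0)
        hsum = h.reindex(sorted(hosts[phylum])).fillna(0.0).sum(axis=0)
        keep = (vsum > 0) & (hsum > 0)
        x, y = hsum[keep].to_numpy(), vsum[keep].to_numpy()
        if keep.sum() < 3 or np.std(x) == 0 or np.std(y) == 0:
            out[phylum] = None
            continue
        r, p = stats.pearsonr(x, y)
        out[phylum] = (float(r), float(p))
    return out


def host_viral_range(
    links: Sequence[VirusHostLink],
    phylum_map: Mapping[str, str],
) -> pd.DataFrame:
    """Mean host range and viral range per host phylum.

    Host range of a virus = number of distinct host populations it links
    to (over the whole network); viral range of a host = number of distinct
    virus populations linking to it. Lineage means are over viruses linked
    to the phylum and over the phylum's linked hosts, respectively.
    """
    if not links:
        return pd.DataFrame(columns=["host_range_mean", "viral_range_mean"])
    host_range: dict[str, set[str]] = {}
    viral_range: dict[str, set[str]] = {}
    for l in links:
        host_range.setdefault(l.virus_population, set()).add(l.host_population)
        viral_range.setdefault(l.host_population, set()).add(l.virus_population)
    rows = {}
    phyla = sorted({phylum_map[h] for h in viral_range if h in phylum_map})
    for phylum in phyla:
        hosts = [h for h in viral_range if phylum_map.get(h) == phylum]
        viruses = sorted({v for h in hosts for v in viral_range[h]})
        rows[phylum] = {
            "host_range_mean": float(np.mean([len(host_range[v]) for v in viruses])),
            "viral_range_mean": float(np.mean([len(viral_range[h]) for h in hosts])),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def lifestyle_ratio_trend(
    virus_abund: AbundanceMatrix,
    lifestyles: Mapping[str, str],
    prokaryote_totals: pd.Series,
) -> dict:
    """Per-sample summed relative abundance of virulent and temperate
    viruses, and their least-squares trends against total prokaryotic
    abundance.

    Returns a dict with ``relative_abundance`` (DataFrame, samples x
    {virulent, temperate}) and ``slopes`` mapping class -> (slope,
    two-tailed p). Viruses labelled "unknown" are excluded; if no virus has
    a known label this is an error.
    """
    v = virus_abund.to_frame()
    labelled = {e: lifestyles.get(e, "unknown") for e in virus_abund.entities}
    known = [e for e, l in labelled.items() if l in ("virulent", "temperate")]
    if not known:
        raise ValueError("no virus carries a virulent/temperate label")
    sub = v.loc[known]
    total = sub.sum(axis=0)
    rel = pd.DataFrame(index=v.columns, columns=["virulent", "temperate"], dtype=float)
    for cls in ("virulent", "temperate"):
        members = [e for e in known if labelled[e] == cls]
        clsum = sub.loc[members].sum(axis=0) if members else pd.Series(0.0, index=v.columns)
        rel[cls] = np.where(total > 0, clsum / total.replace(0, np.nan), 0.0)
    x = prokaryote_totals.reindex(rel.index).to_numpy(float)
    slopes = {}
    for cls in ("virulent", "temperate"):
        y = rel[cls].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            slopes[cls] = (0.0, 1.0)
            continue
        res = stats.linregress(x[ok], y[ok])
        slopes[cls] = (float(res.slope), float(res.pvalue))
    return {"relative_abundance": rel, "slopes": slopes}


def lifestyle_ratio_by_lineage(
    virus_abund: AbundanceMatrix,
    lifestyles: Mapping[str, str],
    links: Sequence[VirusHostLink],
    phylum_map: Mapping[str, str],
) -> pd.Series:
    """Virulent:temperate summed-abundance ratio of the viruses linked to
    each host phylum (NaN when no temperate abundance)."""
    v = virus_abund.to_frame()
    _, viruses = _phylum_groups(links, phylum_map)
    out = {}
    for phylum, vs in sorted(viruses.items()):
        vir = sum(v.loc[e].sum() for e in vs if lifestyles.get(e) == "virulent" and e in v.index)
        tem = sum(v.loc[e].sum() for e in vs if lifestyles.get(e) == "temperate" and e in v.index)
        out[phylum] = vir / tem if tem > 0 else np.nan
    return pd.Series(out, name="virulent_temperate_ratio")


def compare_groups_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Unpaired two-sided Wilcoxon (Mann-Whitney U) comparison."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def quadratic_fit(x: np.ndarray, y: np.ndarray, degree: int = 2) -> dict:
    """Polynomial fit of viral against prokaryotic abundance with adjusted R^2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    coeffs = np.polyfit(x, y, degree)
    pred = np.polyval(coeffs, x)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n, k = len(x), degree
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else np.nan
    adj = 1 - (1 - r2) * (n - 1) / (n - k - 1) if n > k + 1 else np.nan
    return {"coefficients": coeffs.tolist(), "r2": r2, "adjusted_r2": adj}


def summarize_lineages(
    virus_abund: AbundanceMatrix,
    host_abund: AbundanceMatrix,
    links: Sequence[VirusHostLink],
    phylum_map: Mapping[str, str],
    lifestyles: Mapping[str, str] | None = None,
) -> list[LineageSummary]:
    """Full per-lineage summary table (VHR, correlation, ranges, lifestyle)."""
    vhrs = lineage_vhr(virus_abund, host_abund, links, phylum_map)
    corr = lineage_abundance_correlation(virus_abund, host_abund, links, phylum_map)
    ranges = host_viral_range(links, phylum_map)
    ratios = (
        lifestyle_ratio_by_lineage(virus_abund, lifestyles, links, phylum_map)
        if lifestyles
        else pd.Series(dtype=float)
    )
    hosts, viruses = _phylum_groups(links, phylum_map)
    out = []
    for phylum, series in vhrs.items():
        out.append(
            LineageSummary(
                phylum=phylum,
                n_host_populations=len(hosts.get(phylum, ())),
                n_virus_populations=len(viruses.get(phylum, ())),
                vhr_per_sample=series,
                mean_log10_vhr=float(np.log10(series).mean()) if len(series) else np.nan,
                abundance_correlation=corr.get(phylum),
                host_range_mean=ranges["host_range_mean"].get(phylum) if len(ranges) else None,
                viral_range_mean=ranges["viral_range_mean"].get(phylum) if len(ranges) else None,
                virulent_temperate_ratio=ratios.get(phylum) if len(ratios) else None,
            )
        )
    return out
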