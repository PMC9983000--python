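"""Shared machinery for the TOF and sector scan engines.

Both engines reduce to the same loop: for every scan line, place each
precursor at a lateral position ``d`` determined by the scanned parameter
(delay or pulse length), evaluate the fragmentation pattern there, and
accumulate intensity into per-channel transients.  The only difference is
the ``d(scan)`` law, so the channel bookkeeping, the deterministic /
stochastic accumulation, and the event log live here.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .kinematics import PrecursorSpecies

PRECURSOR = "precursor"
FRAGMENT = "fragment"


def build_channels(mixture: Sequence[PrecursorSpecies]):
    """Channel table for a mixture: one channel per distinct fragment m/z
    plus one depleted-precursor channel per precursor.

    Returns ``(channel_mz, channel_kind, routing)`` where ``routing`` maps
    ``(precursor_index) -> (fragment column indices, branching array,
    precursor column index)``.  Distinct species contributing the same m/z
    share a column (their intensities sum); such collisions are reported so
    the cube metadata can flag them.
    """
    entries: list[tuple[float, str]] = []
    for p in mixture:
        for fmz, _ in p.fragments:
            entries.append((fmz, FRAGMENT))
        entries.append((p.mz, PRECURSOR))
    # channels keyed by (mz, kind): a fragment that coincides with another
    # precursor's m/z stays a separate channel from that precursor channel.
    keys = sorted(set(entries), key=lambda k: (k[0], k[1]))
    index = {k: i for i, k in enumerate(keys)}
    channel_mz = np.array([k[0] for k in keys])
    channel_kind = np.array([k[1] for k in keys])

    routing = []
    seen_sources: dict[tuple[float, str], int] = {}
    overlaps: set[float] = set()
    for pi, p in enumerate(mixture):
        cols = np.array(
            [index[(fmz, FRAGMENT)] for fmz, _ in p.fragments], dtype=int
        )
        brs = np.array([br for _, br in p.fragments])
        pcol = index[(p.mz, PRECURSOR)]
        for fmz, _ in p.fragments:
            key = (fmz, FRAGMENT)
            if seen_sources.get(key, pi) != pi:
                overlaps.add(fmz)
            seen_sources[key] = pi
        if seen_sources.get((p.mz, PRECURSOR), pi) != pi:
            overlaps.add(p.mz)
        seen_sources[(p.mz, PRECURSOR)] = pi
        routing.append((cols, brs, pcol))
    return channel_mz, channel_kind, routing, sorted(overlaps)


def accumulate(
    mixture: Sequence[PrecursorSpecies],
    positions: np.ndarray,
    intensities: np.ndarray,
    mode: str,
    seed: Optional[int],
    n_ions: int,
    collect_events: bool,
):
    """Fill the scans x channels intensity matrix from per-precursor
    fragmentation intensities.

    Parameters
    ----------
    positions, intensities :
        ``(n_precursors, n_scans)`` arrays of lateral position (m) and
        pattern intensity ``I(d)`` sampled at the start of the fragmentation
        period of each scan.
    mode :
        ``"deterministic"`` — each fragment channel of precursor ``p``
        receives ``abundance * branching * I(d)`` and the depleted precursor
        channel ``abundance * (1 - I(d))``; ``"stochastic"`` — ``n_ions``
        copies of each precursor fragment as independent Bernoulli(I) draws,
        routed to channels by a multinomial over branching ratios.
    """
    if mode not in ("deterministic", "stochastic"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if mode == "stochastic":
        if seed is None:
            raise ConfigurationError("stochastic mode requires a seed")
        if n_ions < 1:
            raise ConfigurationError("n_ions must be >= 1")
        rng = np.random.default_rng(seed)

    n_prec, n_scans = intensities.shape
    channel_mz, channel_kind, routing, overlaps = build_channels(mixture)
    cube = np.zeros((n_scans, channel_mz.size))
    event_intensity = np.empty_like(intensities)

    for pi, p in enumerate(mixture):
        cols, brs, pcol = routing[pi]
        inten = intensities[pi]
        if mode == "deterministic":
            if cols.size:
                cube[:, cols] += p.abundance * inten[:, None] * brs[None, :]
            cube[:, pcol] += p.abundance * (1.0 - inten)
            event_intensity[pi] = inten
        else:
            fragmented = rng.binomial(n_ions, inten)
            survivors = n_ions - fragmented
            cube[:, pcol] += p.abundance * survivors / n_ions
            if cols.size:
                total_br = brs.sum()
                pvals = np.append(brs, max(1.0 - total_br, 0.0))
                pvals = pvals / pvals.sum()
                counts = rng.multinomial(fragmented, pvals)[:, :-1]
                cube[:, cols] += p.abundance * counts / n_ions
            event_intensity[pi] = fragmented / n_ions

    events = None
    if collect_events:
        scan_idx = np.tile(np.arange(n_scans), n_prec)
        events = pd.DataFrame(
            {
                "scan_index": scan_idx,
                "ion_id": np.repeat(np.arange(n_prec), n_scans),
                "precursor_mz": np.repeat([p.mz for p in mixture], n_scans),
                "lateral_position_m": positions.ravel(),
                "fragmentation_intensity": event_intensity.ravel(),
            }
        ).sort_values(["scan_index", "ion_id"], ignore_index=True)
    return cube, channel_mz, channel_kind, overlaps, events
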