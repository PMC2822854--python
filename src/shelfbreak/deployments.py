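"""Deployment log of the February 2006 Great Barrier Island GPS-tracking
campaign on breeding Black Petrels.

Fourteen loggers were deployed on chick-rearing adults; some were lost at
sea or recovered without usable data. The per-bird record (ring number,
burrow, deployment/recovery dates, deployment length in days, body mass at
deployment and recovery) is transcribed here so deployment-level summaries
and the "recovered with data" filter are reproducible without the raw
fieldwork notes. A missing mass or day count is ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional


@dataclass(frozen=True)
class DeploymentRecord:
    ring: str
    burrow: str
    deployed: str
    recovered: str            # a date, "Tracker Lost", or "Returned Later"
    days: Optional[int]
    mass_deploy_g: Optional[float]
    mass_recover_g: Optional[float]
    data_recovered: bool      # False: tracker lost or recovered without data


DEPLOYMENT_LOG: List[DeploymentRecord] = [
    DeploymentRecord("25459", "144", "26 February", "2 March", 4, 900, 850, True),
    DeploymentRecord("25659", "101", "2 March", "4 March", 2, 700, 660, True),
    DeploymentRecord("25421", "75", "2 March", "3 March", 1, 855, 785, True),
    DeploymentRecord("25507", "140", "23 February", "6 March", 11, 600, 660, True),
    DeploymentRecord("30854", "7", "24 February", "8 March", 12, 680, None, False),
    DeploymentRecord("31155", "81", "26 February", "Tracker Lost", None, 585, None, False),
    DeploymentRecord("31103", "8", "23 February", "1 March", 6, 700, 740, True),
    DeploymentRecord("31272", "7", "24 February", "1 March", 5, 850, 770, True),
    DeploymentRecord("32005", "68", "2 March", "Returned Later", None, 665, None, True),
    DeploymentRecord("33312", "265", "24 February", "Tracker Lost", None, 580, None, False),
    DeploymentRecord("33715", "316", "23 February", "25 February", 2, 660, 795, True),
    DeploymentRecord("33757", "244", "24 February", "28 February", 4, 660, 790, True),
    DeploymentRecord("33759", "257", "23 February", "Tracker Lost", None, 610, None, False),
    DeploymentRecord("34999", "204", "24 February", "Tracker Lost", None, 690, None, False),
]


def successful_deployments(log: Optional[List[DeploymentRecord]] = None) -> List[DeploymentRecord]:
    """Deployments whose tracker was recovered with data — the set that
    yields analysable foraging tracks."""
    return [r for r in (log if log is not None else DEPLOYMENT_LOG) if r.data_recovered]
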