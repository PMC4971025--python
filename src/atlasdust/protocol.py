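"""The automated correction protocol: Stage-2 then Stage-4 cleanup runs.

The full atlas-correction procedure interleaves manual editing with two
fully automatic cleanup stages; only the automatic stages live here. The
defaults ship in ``data/protocol.yaml`` and can be overridden with a user
YAML file of the same shape:

* Stage 2 — eradicate the suspicious label's dust: S = 6, face
  connectivity, no dilation, force on, review = {suspicious label}.
* Stage 4 — remove isolated dust from all labels: S = 5, full
  connectivity, dilation on, force on, exclude user-supplied labels whose
  disconnected bodies are anatomically viable (e.g. CSF).
"""

from __future__ import annotations

from importlib import resources
from typing import Sequence

import yaml

from .cleanup import ChangeLog, CleanupConfig, cleanup_dust
from .report import stage_report
from .volumes import IntensityVolume, LabelVolume

__all__ = ["load_protocol", "run_protocol"]


def load_protocol(
    path: str | None = None,
    suspicious_label: int | None = None,
    csf_like_labels: Sequence[int] = (),
) -> tuple[int, list[tuple[str, CleanupConfig]]]:
    """Parse a protocol YAML into named CleanupConfigs.

    The placeholder review entry ``suspicious`` resolves to the suspicious
    label ID, and the exclude entry ``csf`` to ``csf_like_labels``.
    Returns ``(suspicious_label, [(stage_name, config), ...])``.
    """
    if path is None:
        text = resources.files("atlasdust").joinpath("data/protocol.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    suspicious = int(suspicious_label if suspicious_label is not None
                     else doc.get("suspicious_label", 999))

    def resolve(entries) -> tuple[int, ...] | None:
        if entries in (None, "all"):
            return None
        out: list[int] = []
        for e in entries:
            if e == "suspicious":
                out.append(suspicious)
            elif e == "csf":
                out.extend(int(c) for c in csf_like_labels)
            else:
                out.append(int(e))
        return tuple(out)

    stages = []
    for st in doc["stages"]:
        review = resolve(st.get("review", "all"))
        exclude = resolve(st.get("exclude", [])) or None
        stages.append((
            str(st["name"]),
            CleanupConfig(
                max_island_voxel_count=int(st["max_island_voxel_count"]),
                labels_to_review=review,
                labels_to_exclude=exclude,
                use_dilation=bool(st.get("use_dilation", True)),
                connectivity=st.get("connectivity", "full"),
                force_relabel=bool(st.get("force_relabel", False)),
            ),
        ))
    return suspicious, stages


def run_protocol(
    v: LabelVolume,
    intensities: Sequence[IntensityVolume],
    suspicious_label: int = 999,
    csf_like_labels: Sequence[int] = (),
    config_path: str | None = None,
) -> tuple[LabelVolume, dict]:
    """Run the automated stages in order; returns the final volume + report.

    The report contains per-stage suspicious-voxel counts and reductions
    (see :func:`atlasdust.report.stage_report`), the per-stage ChangeLogs,
    and the per-stage volumes.
    """
    suspicious, stages = load_protocol(
        config_path, suspicious_label=suspicious_label,
        csf_like_labels=csf_like_labels)
    volumes: list[tuple[str, LabelVolume]] = [("base", v)]
    logs: dict[str, ChangeLog] = {}
    current = v
    for name, cfg in stages:
        current, log = cleanup_dust(current, list(intensities), cfg)
        volumes.append((name, current))
        logs[name] = log
    result = {
        "report": stage_report(volumes, suspicious_label=suspicious),
        "logs": logs,
        "volumes": volumes,
    }
    return current, result
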