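"""Session-level dataset containers and train/validation/test splitting.

A *session* is one 60-s propulsion trial of one participant in one
wheelchair configuration and pushing style, carried as a
:class:`~wheelload.kinematics.FeatureFrame`. Splits are assigned at the
session level — every sample of a session lives in exactly one of train,
validation or test — and held-out participants or configurations go to
the test split wholesale, so the test set contains only unseen subjects
and unseen conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import FeatureFrame

__all__ = ["Session", "SessionDataset", "split_sessions"]


@dataclass
class Session:
    participant_id: str
    session_type: str       # wheelchair configuration label
    pushing_style: int      # 1 | 2 | 3
    frame: FeatureFrame
    split: str | None = None      # train | validation | test
    meta: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.session_type, self.pushing_style)


@dataclass
class SessionDataset:
    sessions: list

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    def subset(self, split: str) -> "SessionDataset":
        return SessionDataset([s for s in self.sessions if s.split == split])

    @property
    def participants(self) -> list:
        return sorted({s.participant_id for s in self.sessions})

    @property
    def session_types(self) -> list:
        return sorted({s.session_type for s in self.sessions})


def split_sessions(dataset: SessionDataset,
                   holdout_participants=(),
                   holdout_conditions=(),
                   train_fraction: float = 0.8,
                   seed: int = 0) -> SessionDataset:
    """Assign train/validation/test labels session-wise.

    All sessions of held-out participants or held-out configurations become
    the test split; the remainder is randomly divided into train and
    validation at ``train_fraction``, whole sessions at a time.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    holdout_participants = set(holdout_participants)
    holdout_conditions = set(holdout_conditions)
    unknown_p = holdout_participants - set(dataset.participants)
    unknown_c = holdout_conditions - set(dataset.session_types)
    if unknown_p or unknown_c:
        raise ValueError(
            f"unknown holdouts: participants {sorted(unknown_p)}, "
            f"conditions {sorted(unknown_c)}"
        )
    rng = np.random.default_rng(seed)
    test, rest = [], []
    for s in dataset.sessions:
        if (s.participant_id in holdout_participants
                or s.session_type in holdout_conditions):
            test.append(replace(s, split="test"))
        else:
            rest.append(s)
    order = rng.permutation(len(rest))
    n_train = int(round(train_fraction * len(rest)))
    out = list(test)
    shuffled = [rest[i] for i in order]
    for i, s in enumerate(shuffled):
        out.append(replace(s, split="train" if i < n_train else "validation"))
    out.sort(key=lambda s: s.key)
    return SessionDataset(out)
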