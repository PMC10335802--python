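"""In-process publish/subscribe broker mediating between graphs.

Publishing never blocks on subscribers; consumers drain per-topic FIFO
queues.  Delivery order within a topic equals publication order.
"""

from __future__ import annotations

from collections import deque


class Broker:
    """Topic -> FIFO queue of ``(timestamp, data)`` items."""

    def __init__(self):
        self._topics: dict[str, deque] = {}
        self._published: dict[str, int] = {}
        self._drained: dict[str, int] = {}

    def publish(self, topic: str, data, timestamp: float = 0.0) -> None:
        """Append an item to *topic*'s queue; topics auto-create."""
        self._topics.setdefault(topic, deque()).append((timestamp, data))
        self._published[topic] = self._published.get(topic, 0) + 1

    def drain(self, topic: str) -> list:
        """Return all pending items of *topic* in publication order and empty it.

        Draining an unknown topic returns an empty list.
        """
        queue = self._topics.get(topic)
        if not queue:
            return []
        items = list(queue)
        queue.clear()
        self._drained[topic] = self._drained.get(topic, 0) + len(items)
        return items

    def pending(self, topic: str) -> int:
        return len(self._topics.get(topic, ()))

    def published_count(self, topic: str) -> int:
        return self._published.get(topic, 0)

    def drained_count(self, topic: str) -> int:
        return self._drained.get(topic, 0)

    def topics(self) -> list:
        return sorted(self._topics)
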