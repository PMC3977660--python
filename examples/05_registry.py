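"""Run a registry over two live local services and refresh their counts.

The registry is the directory a federated client consults: who serves
interactions, where, whether they are up, and how many records they hold.
refresh_counts polls each service's count endpoint for the match-all query
and marks unreachable services inactive.
"""

from psicquic_lite import (
    PsicquicApp, ServiceEntry, build_index, refresh_counts, registry_query,
    start_background_server,
)
from psicquic_lite.fixtures import FixtureSpec, generate

servers, entries = [], []
for name, n, seed in (("service-one", 80, 1), ("service-two", 50, 2)):
    records, _ = generate(FixtureSpec(n_records=n, seed=seed))
    server, _, base = start_background_server(
        PsicquicApp(build_index(records, dialect="2.7")))
    servers.append(server)
    entries.append(ServiceEntry(name, base + "/current/search/",
                                tags=("synthetic",), version="1.0.0"))
entries.append(ServiceEntry("service-down",
                            "http://127.0.0.1:9/current/search/"))

refreshed = refresh_counts(entries, timeout=5)
for server in servers:
    server.shutdown()

print("after refresh:")
for entry in refreshed:
    state = "active" if entry.active else "INACTIVE"
    print(f"  {entry.name}: {entry.interaction_count} interactions ({state})")
print("registry total:",
      sum(e.interaction_count for e in refreshed), "interactions")

print("\nACTIVE listing (txt format):")
print(registry_query(refreshed, "ACTIVE", "txt"), end="")
# Counts reflect each service's visible records (negative evidences are
# hidden from the match-all query); a dead endpoint flips to INACTIVE
# instead of failing the refresh.
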