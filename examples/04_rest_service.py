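"""Serve an indexed collection over the PSICQUIC REST contract.

Starts the WSGI service on a local port, then queries it exactly as any
federated client would: MIQL in the URL path, format/paging as query
parameters, total match count in the X-PSICQUIC-Count header.
"""

import urllib.request

from psicquic_lite import PsicquicApp, build_index, start_background_server
from psicquic_lite.fixtures import FixtureSpec, generate

records, _ = generate(FixtureSpec(n_records=100, seed=5))
app = PsicquicApp(build_index(records, dialect="2.7"),
                  provider_name="example-provider")
server, _, base = start_background_server(app)
print(f"service running at {base}/current/search/\n")


def get(path):
    with urllib.request.urlopen(base + path) as response:
        return response.read().decode(), dict(response.headers)


body, headers = get("/current/search/query/species:9606?format=count")
print(f"count for species:9606: {body}  (header: "
      f"{headers['X-PSICQUIC-Count']})")

body, _ = get("/current/search/query/species:9606?format=tab27&maxResults=2")
print("first two MITAB 2.7 rows (truncated):")
for line in body.splitlines():
    print(" ", line[:100], "...")

body, _ = get("/current/search/formats")
print("formats:", " ".join(body.split()))

body, _ = get("/current/search/property/psicquic.record.count")
print("records served:", body)

xgmml, _ = get("/current/search/query/taxidA:9606?format=xgmml")
print(f"xgmml export: {xgmml.count('<node')} nodes, "
      f"{xgmml.count('<edge')} edges")
server.shutdown()
# The interactor/interaction endpoints are sugar for identifier:"..." and
# interaction_id:"..." queries and return byte-identical bodies.
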