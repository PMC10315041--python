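{
  "@context": {
    "schema": "http://schema.org/",
    "bsp": "https://bioschemas.org/profiles#",
    "name": "schema:name",
    "targetClass": {"@id": "bsp:targetClass", "@type": "@id"},
    "properties": "bsp:properties",
    "property": {"@id": "bsp:property", "@type": "@id"},
    "marginality": "bsp:marginality"
  },
  "@id": "https://bioschemas.org/profiles/Gene/1.0-RELEASE",
  "@type": "bsp:Profile",
  "name": "Gene",
  "targetClass": "http://schema.org/Gene",
  "properties": [
    {"property": "http://schema.org/identifier", "marginality": "minimum"},
    {"property": "http://schema.org/name", "marginality": "minimum"},
    {"property": "http://schema.org/description", "marginality": "recommended"},
    {"property": "http://schema.org/url", "marginality": "recommended"}
  ]
}
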