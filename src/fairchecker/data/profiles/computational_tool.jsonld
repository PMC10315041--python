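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
  "@id": "https://bioschemas.org/profiles/ComputationalTool/1.0-RELEASE",
  "@type": "bsp:Profile",
  "name": "ComputationalTool",
  "targetClass": "http://schema.org/SoftwareApplication",
  "properties": [
    {"property": "http://schema.org/name", "marginality": "minimum"},
    {"property": "http://schema.org/description", "marginality": "minimum"},
    {"property": "http://schema.org/url", "marginality": "minimum"},
    {"property": "http://schema.org/applicationCategory", "marginality": "recommended"},
    {"property": "http://schema.org/citation", "marginality": "recommended"},
    {"property": "http://schema.org/downloadUrl", "marginality": "recommended"},
    {"property": "http://schema.org/featureList", "marginality": "recommended"},
    {"property": "http://schema.org/operatingSystem", "marginality": "recommended"},
    {"property": "http://schema.org/softwareVersion", "marginality": "recommended"},
    {"property": "http://schema.org/identifier", "marginality": "optional"},
    {"property": "http://schema.org/applicationSubCategory", "marginality": "optional"},
    {"property": "http://schema.org/softwareHelp", "marginality": "optional"}
  ]
}
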