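{
 "files": {
  "core_metabolites.tsv": "91f0c9a781933c9a1b188a7ac88713d76427b84b55fa63e5bb2a5cae7f3eca0c",
  "core_reactions.tsv": "ffc2dcf61e5a5b15bba888ce14ff45069cf4c38a65a681baa9c225db714a1b59",
  "de_table.tsv": "bfd82ab52c7898f4e681f2bd50430cb117a79816a19e2f3c63b74b2b78217a29",
  "de_truth.tsv": "4428f3803ed0c0745f00b75d62e5afc85920db5a15dd0713054b35bb1a821a5a",
  "network_1.tsv": "9b6317930d2518b721ebc2295524c4cd13dd9e64d4adb054e8f7edfa55ddb1b2",
  "network_2.tsv": "6353c29dc80b8370e5f40a02c8c6b1ca073a51ef46c6df99e9ec08f7c173cf90",
  "network_3.tsv": "87e3482c84ab9e44c61780eb7cd73db484e35b6f9b3fb84cc864b0d846c856f4"
 },
 "seed": 20230123
}
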