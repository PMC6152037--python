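{
 "dHsolv.tsv": "c20048f1d43188cfe378aaafe18740ce474e8cf12eb1c3e6a61f6b8e06cea00c",
 "dHsub.tsv": "041acbb00fe13fbde51a77604528853fc3020d672b0c56bbceb574a760b1c25a",
 "dHvap.tsv": "4717de4dbb3f5c9f6e52cb89a022298abcb72eb1232b32bcc18a6ac23fa5e4eb",
 "dSfus.tsv": "3bdbabd94c28cda325edce95972ee5a95e2218bdb1c0833bf5e8b6e415adc035",
 "reported_stats.tsv": "9647d81ba6310090367f13f8bed2d63fb73c56113d9c9de5e3fa28c60709517d",
 "tpcE.tsv": "aebce6b73ef7a3484f5a3a586a756d41c4c1967d5a34f9ee4f396746b65f559d"
}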