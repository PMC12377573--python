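child_code	parent_code	child_term
202852009	239955008	Shoulder tendinitis
239955008	76318008	Tendinitis AND/OR tenosynovitis of the shoulder region
76318008	900000011	Disorder of tendon of shoulder region
900000011	900000012	synthetic attachment node
900000012	900000013	synthetic attachment node
900000013	404684003	synthetic attachment node
58150001	900000021	Fracture of clavicle
900000021	900000022	synthetic attachment node
900000022	900000023	synthetic attachment node
900000023	404684003	synthetic attachment node
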