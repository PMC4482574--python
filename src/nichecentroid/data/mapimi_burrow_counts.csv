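id,district,count
Americanos,"I: Los Americanos, Coahuila",8
Las Flores,"I: Los Americanos, Coahuila",2
Lagunetas,"I: Los Americanos, Coahuila",4
La Mena,"I: Los Americanos, Coahuila",3
Cerros Emilio,"II: Sierra del Diablo, Chihuahua",8
Ejido Emiliano Zapata,"II: Sierra del Diablo, Chihuahua",2
La Parva,"II: Sierra del Diablo, Chihuahua",2
Los Remedios,"VI: Sierra de los Remedios, Chihuahua",1
San Miguel,"III: Rancho Diana, Chihuahua",4
Ejido Vicente Guerrero,"III: Rancho Diana, Chihuahua",2
El Pujo,"V: MBR, Durango-Coahuila-Chihuahua",11
Tortugas,"V: MBR, Durango-Coahuila-Chihuahua",10
La Flor (Brecha),"V: MBR, Durango-Coahuila-Chihuahua",13
Las Lolas,"V: MBR, Durango-Coahuila-Chihuahua",18
Cajones,"V: MBR, Durango-Coahuila-Chihuahua",20
La Flor (Bebedero),"V: MBR, Durango-Coahuila-Chihuahua",17
La Flor (Joyita),"V: MBR, Durango-Coahuila-Chihuahua",17
San Ignacio Yermo,"V: MBR, Durango-Coahuila-Chihuahua",11
Laboratory MBR North,"V: MBR, Durango-Coahuila-Chihuahua",8
Laboratory MBR South,"V: MBR, Durango-Coahuila-Chihuahua",11
La Soledad,"V: MBR, Durango-Coahuila-Chihuahua",3
San Carlos,"V: MBR, Durango-Coahuila-Chihuahua",5
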