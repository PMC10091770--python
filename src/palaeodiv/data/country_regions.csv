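country,region
United Kingdom,UK & Ireland
UK,UK & Ireland
England,UK & Ireland
Scotland,UK & Ireland
Wales,UK & Ireland
Northern Ireland,UK & Ireland
Ireland,UK & Ireland
France,Western Europe
Belgium,Western Europe
Netherlands,Western Europe
Luxembourg,Western Europe
Spain,Western Europe
Portugal,Western Europe
Italy,Western Europe
Switzerland,Western Europe
Norway,Western Europe
Sweden,Western Europe
Denmark,Western Europe
Germany,Central Europe
Austria,Central Europe
Czech Republic,Central Europe
Czechia,Central Europe
Slovakia,Central Europe
Poland,Central Europe
Hungary,Central Europe
Slovenia,Central Europe
Russia,Eastern Europe
Russian Federation,Eastern Europe
Ukraine,Eastern Europe
Belarus,Eastern Europe
Estonia,Eastern Europe
Latvia,Eastern Europe
Lithuania,Eastern Europe
Moldova,Eastern Europe
United States,North America
USA,North America
US,North America
Canada,North America
Mexico,North America
Greenland,North America
South Africa,Africa
Morocco,Africa
Algeria,Africa
Egypt,Africa
Niger,Africa
Ghana,Africa
Zimbabwe,Africa
Madagascar,Africa
China,Asia
Mongolia,Asia
Kazakhstan,Asia
Iran,Asia
Turkey,Asia
Saudi Arabia,Asia
Oman,Asia
India,Asia
Pakistan,Asia
Vietnam,Asia
Japan,Asia
Thailand,Asia
Brazil,South America
Argentina,South America
Bolivia,South America
Chile,South America
Peru,South America
Uruguay,South America
Paraguay,South America
Venezuela,South America
Colombia,South America
Australia,Oceania
New Zealand,Oceania
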